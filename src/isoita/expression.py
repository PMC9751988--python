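"""Count normalization, 5'-isomiR aggregation, and expression filtering.

Count matrices are pandas DataFrames with features in rows and samples in
columns.  Fractional expected counts (e.g. RSEM ``expected_count``) are
accepted as-is.  Normalization follows the median-of-ratios size-factor
scheme with FPM/FPKM scaling and an optional ``log2(x + 1)`` transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seed_model import IsomiRId

_LOG = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """A normalized expression matrix tagged with its scheme and log state."""

    data: pd.DataFrame
    normalization: str  # "FPM" or "FPKM"
    log2: bool = False

    def log_transform(self) -> "NormalizedMatrix":
        """Return a ``log2(x + 1)``-transformed copy (values stay >= 0)."""
        if self.log2:
            raise ValueError("matrix is already log2-transformed")
        return NormalizedMatrix(np.log2(self.data + 1.0), self.normalization, log2=True)


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors by the median-of-ratios algorithm.

    For each feature with strictly positive counts in every sample, compute
    its geometric mean across samples; each sample's factor is the median
    over those reference features of count / geometric mean.  Fails loudly
    when no feature is positive in all samples (no pseudo-reference
    fallback is applied).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; median-of-ratios "
            "is undefined (a pseudo-reference fallback is deliberately not applied)"
        )
    log_counts = np.log(counts.loc[all_positive].to_numpy(dtype=float))
    log_ratios = log_counts - log_counts.mean(axis=1, keepdims=True)
    factors = pd.Series(np.exp(np.median(log_ratios, axis=0)), index=counts.columns, name="size_factor")
    return factors


def normalize(
    counts: pd.DataFrame,
    factors: pd.Series,
    mode: str = "FPM",
    lengths: "pd.Series | None" = None,
) -> NormalizedMatrix:
    """Size-factor-normalize counts and scale to FPM or FPKM.

    FPM scales size-factor-divided counts to per-million of the mean
    normalized library size; FPKM additionally divides by feature length in
    kilobases (``lengths`` in nucleotides, required and positive).
    """
    if mode not in ("FPM", "FPKM"):
        raise ValueError(f"mode must be 'FPM' or 'FPKM', got {mode!r}")
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    normed = counts.div(factors.reindex(counts.columns), axis=1)
    mean_lib = normed.sum(axis=0).mean()
    if mean_lib <= 0:
        raise ValueError("mean normalized library size is zero")
    fpm = normed * (1e6 / mean_lib)
    if mode == "FPM":
        return NormalizedMatrix(fpm, "FPM")
    if lengths is None:
        raise ValueError("FPKM mode requires per-feature lengths")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"FPKM mode: missing lengths for features {missing}")
    if (lengths <= 0).any():
        raise ValueError("FPKM mode requires positive lengths")
    return NormalizedMatrix(fpm.div(lengths / 1e3, axis=0), "FPKM")


def aggregate_5prime_isomirs(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum 3'-variant counts into 5'-isomiR rows.

    Rows are keyed ``"name|shift"`` or ``"name|shift|<3'-variant tag>"``;
    3'-end variation leaves the seed untouched, so variants sharing
    ``(name, shift)`` are summed element-wise.  The total matrix sum is
    preserved exactly.  Row order follows first appearance.
    """

    def canonical(label) -> str:
        parts = str(label).split("|")
        if len(parts) < 2:
            raise ValueError(f"malformed isomiR key {label!r}: expected 'name|shift[|variant]'")
        try:
            return str(IsomiRId(parts[0], int(parts[1])))
        except ValueError as exc:
            raise ValueError(f"malformed isomiR key {label!r}: {exc}") from exc

    keys = [canonical(i) for i in counts.index]
    out = counts.groupby(pd.Index(keys, name=counts.index.name), sort=False).sum()
    return out


def select_top_isomirs(median_expr: pd.Series, coverage: float = 0.99) -> list:
    """Smallest set of top-expressed isomiRs covering a fraction of total median.

    IsomiRs are sorted by median expression descending (ties broken
    lexicographically by id); the shortest prefix whose median sum reaches
    ``coverage`` times the total is returned.
    """
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    total = float(median_expr.sum())
    if total <= 0:
        _LOG.warning("select_top_isomirs: all medians are zero; returning empty list")
        return []
    order = sorted(median_expr.index, key=lambda i: (-median_expr[i], str(i)))
    cum = 0.0
    chosen = []
    for iso in order:
        chosen.append(iso)
        cum += float(median_expr[iso])
        if cum >= coverage * total:
            break
    return chosen


def filter_low_transcripts(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop transcripts with zero counts in strictly more than half the samples.

    Exactly half is retained; the decision depends only on the zero
    pattern, not on magnitudes.
    """
    n_zero = (counts == 0).sum(axis=1)
    keep = n_zero <= counts.shape[1] // 2
    dropped = int((~keep).sum())
    if dropped:
        _LOG.info("filter_low_transcripts: dropped %d of %d transcripts", dropped, len(counts))
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# TSV external interfaces.

def read_count_matrix(path) -> pd.DataFrame:
    """Read a features x samples TSV (first column feature ids, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.index.is_unique:
        raise ValueError(f"duplicate feature ids in {path}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative entries in count matrix {path}")
    return df


def read_sample_groups(path) -> pd.Series:
    """Read a sample->group TSV with columns ``sample_id``, ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ValueError("sample-group table must have columns ['sample_id', 'group']")
    if df["sample_id"].duplicated().any():
        raise ValueError("each sample must have exactly one group label")
    return df.set_index("sample_id")["group"]
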