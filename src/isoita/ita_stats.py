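"""IsomiR targeting activity (ITA) statistics.

For each 5'-isomiR and sample group, Spearman correlations between the
isomiR's expression and every predicted-target and non-target transcript
are computed, BH-adjusted jointly, and thresholded (rho < -0.3 and
FDR < 0.05, both strict) to count anti-correlated transcripts:

* ``n_tar`` / ``m_tar`` — predicted targets and the anti-correlated subset;
* ``n_nontar`` / ``m_nontar`` — the same over the negative-control
  non-target set;
* ``ITA = m_tar``;
* ``background ITA = n_tar * m_nontar / n_nontar`` — the number of
  anti-correlated targets expected if targets behaved like the background;
* ``adjusted ITA = m_tar - n_tar * m_nontar / n_nontar``.

Significance of an isomiR's activity over background is assessed with a
one-sided Fisher's exact test on the 2x2 table
``[[m_tar, n_tar - m_tar], [m_nontar, n_nontar - m_nontar]]`` (alternative:
the anti-correlated fraction is greater among targets), BH-adjusted across
isomiRs within each sample group and stratum.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_LOG = logging.getLogger(__name__)

ITA_COLUMNS = [
    "isomir", "group", "stratum", "n_tar", "m_tar", "n_nontar", "m_nontar",
    "ita", "background_ita", "adjusted_ita", "adjusted_ita_signed_log",
    "fisher_p", "fisher_fdr",
]


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Spearman correlation with mid-rank tie handling and t-approximation p.

    Returns ``(rho, p)``; for a constant vector the correlation is
    undefined and ``(nan, nan)`` is returned so callers can exclude the
    record.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    res = stats.spearmanr(x, y)
    return (float(res.statistic), float(res.pvalue))


def spearman_matrix(X: np.ndarray, Y: np.ndarray) -> tuple:
    """All-pairs Spearman correlations between rows of ``X`` and rows of ``Y``.

    Both arguments are features x samples arrays over the same samples.
    Computation is the rank-then-Pearson route (mid-ranks for ties) with
    two-sided p-values from the large-sample t approximation, matching
    :func:`scipy.stats.spearmanr` pair by pair.  Rows with constant values
    yield ``nan`` rho and p.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the sample axis")
    n = X.shape[1]
    if n < 3:
        raise ValueError("spearman requires at least 3 samples")

    def centred_ranks(M):
        R = stats.rankdata(M, axis=1).astype(float)
        R -= R.mean(axis=1, keepdims=True)
        norms = np.sqrt((R ** 2).sum(axis=1))
        constant = norms == 0
        norms[constant] = 1.0
        return R / norms[:, None], constant

    Rx, const_x = centred_ranks(X)
    Ry, const_y = centred_ranks(Y)
    rho = np.clip(Rx @ Ry.T, -1.0, 1.0)
    rho[const_x, :] = np.nan
    rho[:, const_y] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    return rho, p


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def count_anticorrelated(
    rho: Iterable[float],
    fdr: Iterable[float],
    rho_max: float = -0.3,
    fdr_max: float = 0.05,
) -> int:
    """Count records with ``rho < rho_max`` and ``fdr < fdr_max`` (both strict)."""
    rho = np.asarray(list(rho), dtype=float)
    fdr = np.asarray(list(fdr), dtype=float)
    return int(((rho < rho_max) & (fdr < fdr_max)).sum())


def _check_table(m_tar: int, n_tar: int, m_nontar: int, n_nontar: int) -> None:
    if n_nontar < 1:
        raise ValueError("n_nontar must be >= 1: no background estimable")
    if n_tar < 1:
        raise ValueError("n_tar must be >= 1")
    if not (0 <= m_tar <= n_tar and 0 <= m_nontar <= n_nontar):
        raise ValueError(
            f"invalid counts: m_tar={m_tar}, n_tar={n_tar}, m_nontar={m_nontar}, n_nontar={n_nontar}"
        )


def adjusted_ita(m_tar: int, n_tar: int, m_nontar: int, n_nontar: int) -> float:
    """ITA minus background ITA: ``m_tar - n_tar * m_nontar / n_nontar``.

    Equals ``m_tar`` when the background is empty, zero when the
    anti-correlated fractions coincide, and goes negative when the
    background fraction exceeds ``m_tar / n_tar`` (e.g. an isomiR whose
    single true target is a hub transcription factor dragging many
    non-targets into anti-correlation by transitivity).
    """
    _check_table(m_tar, n_tar, m_nontar, n_nontar)
    return m_tar - n_tar * m_nontar / n_nontar


def background_ita(m_tar: int, n_tar: int, m_nontar: int, n_nontar: int) -> float:
    """Anti-correlated non-target fraction scaled by the predicted-target count."""
    _check_table(m_tar, n_tar, m_nontar, n_nontar)
    return n_tar * m_nontar / n_nontar


def fisher_one_sided(m_tar: int, n_tar: int, m_nontar: int, n_nontar: int) -> float:
    """One-sided Fisher's exact test for target-enriched anti-correlation.

    The p-value is the hypergeometric tail probability of observing at
    least ``m_tar`` anti-correlated transcripts in the target row of the
    table ``[[m_tar, n_tar - m_tar], [m_nontar, n_nontar - m_nontar]]``
    with all margins fixed (alternative hypothesis: the anti-correlated
    fraction is greater among targets than non-targets).
    """
    _check_table(m_tar, n_tar, m_nontar, n_nontar)
    N = n_tar + n_nontar
    K = m_tar + m_nontar
    return float(stats.hypergeom.sf(m_tar - 1, N, K, n_tar))


def signed_log(y) -> "float | np.ndarray":
    """Signed log transform ``sgn(y) * log2(|y| + 1)`` (odd; fixes 0)."""
    y = np.asarray(y, dtype=float)
    out = np.sign(y) * np.log2(np.abs(y) + 1.0)
    return float(out) if out.ndim == 0 else out


def _target_sets_by_stratum(
    interactions: pd.DataFrame,
    iso_ids: Sequence[str],
    tx_ids: set,
    strata: Sequence[str],
) -> dict:
    """Per-stratum, per-isomiR predicted-target transcript sets.

    With ``"pooled"`` all pairs enter the single stratum ``"all"``; with
    ``"seed_type"`` (or ``"region"``) a pair enters every stratum whose
    label annotates at least one of its sites, so a pair with several site
    types is considered in all corresponding designs.
    """
    known = interactions[
        interactions["isomir"].isin(set(iso_ids)) & interactions["transcript_id"].isin(tx_ids)
    ]
    out: dict = {}
    for mode in strata:
        if mode == "pooled":
            groups = {"all": known}
        elif mode in ("seed_type", "region"):
            groups = {str(label): sub for label, sub in known.groupby(mode, sort=True)}
        else:
            raise ValueError(f"unknown stratum mode {mode!r}; expected pooled/seed_type/region")
        for label, sub in groups.items():
            sets = out.setdefault(label, {})
            for iso, tx in zip(sub["isomir"], sub["transcript_id"]):
                sets.setdefault(iso, set()).add(tx)
    return out


def compute_ita_profile(
    iso_expr: pd.DataFrame,
    tx_expr: pd.DataFrame,
    groups: pd.Series,
    interactions: pd.DataFrame,
    nontargets: Mapping[str, set],
    strata: Sequence[str] = ("pooled",),
    rho_max: float = -0.3,
    fdr_max: float = 0.05,
    min_group_size: int = 100,
    return_correlations: bool = False,
):
    """Per-(isomiR, group, stratum) ITA records with Fisher significance.

    Parameters
    ----------
    iso_expr, tx_expr
        log2(x+1)-transformed normalized expression, features x samples,
        sharing sample columns.
    groups
        Sample -> group label mapping; groups smaller than
        ``min_group_size`` are skipped with a warning.
    interactions
        Unified interaction table (site-level rows).
    nontargets
        isomiR id -> set of non-target transcript ids.  Transcripts also
        appearing among the isomiR's predicted targets are removed from its
        non-target set (a transcript cannot occupy both rows of the 2x2
        table).
    strata
        Any of ``"pooled"``, ``"seed_type"``, ``"region"``; each mode
        contributes its strata to the output (the pooled stratum is
        labelled ``"all"``).

    Within each group, correlation p-values of all target and non-target
    pairs are BH-adjusted jointly; anti-correlation requires
    ``rho < rho_max`` and ``FDR < fdr_max`` (strict).  Constant expression
    vectors are excluded from both numerator and denominator counts with a
    logged tally.  Fisher p-values are BH-adjusted across isomiRs within
    each (group, stratum).
    """
    common = [s for s in iso_expr.columns if s in set(tx_expr.columns) and s in groups.index]
    iso_ids = list(iso_expr.index)
    tx_ids = list(tx_expr.index)
    tx_pos = {t: i for i, t in enumerate(tx_ids)}

    strata_sets = _target_sets_by_stratum(interactions, iso_ids, set(tx_ids), strata)
    all_targets = {
        iso: set().union(*(strata_sets[label].get(iso, set()) for label in strata_sets))
        for iso in iso_ids
    }
    clean_nontargets = {}
    for iso in iso_ids:
        nt = set(nontargets.get(iso, set())) & set(tx_ids)
        overlap = nt & all_targets[iso]
        if overlap:
            _LOG.info("isomiR %s: removed %d predicted targets from its non-target set", iso, len(overlap))
        clean_nontargets[iso] = nt - overlap

    records = []
    corr_frames = []
    for group in pd.unique(groups.loc[common]):
        samples = [s for s in common if groups[s] == group]
        if len(samples) < min_group_size:
            _LOG.warning(
                "group %s has %d samples (< %d); skipped", group, len(samples), min_group_size
            )
            continue
        X = iso_expr.loc[:, samples].to_numpy(dtype=float)
        Y = tx_expr.loc[:, samples].to_numpy(dtype=float)
        rho, p = spearman_matrix(X, Y)
        n_constant = int(np.isnan(rho).all(axis=1).sum() + np.isnan(rho).all(axis=0).sum())
        if n_constant:
            _LOG.info("group %s: %d constant expression vectors excluded", group, n_constant)

        # Joint BH family: every finite target + non-target correlation p.
        rows_idx, cols_idx = [], []
        for i, iso in enumerate(iso_ids):
            # sorted: file outputs must be byte-identical across processes
            for tx in sorted(all_targets[iso] | clean_nontargets[iso]):
                rows_idx.append(i)
                cols_idx.append(tx_pos[tx])
        rows_idx = np.asarray(rows_idx, dtype=int)
        cols_idx = np.asarray(cols_idx, dtype=int)
        family_p = p[rows_idx, cols_idx]
        finite = np.isfinite(family_p)
        fdr = np.full(p.shape, np.nan)
        if finite.any():
            fdr[rows_idx[finite], cols_idx[finite]] = bh_adjust(family_p[finite])

        sig = (rho < rho_max) & (fdr < fdr_max)

        if return_correlations:
            corr_frames.append(
                pd.DataFrame(
                    {
                        "group": group,
                        "isomir": [iso_ids[i] for i in rows_idx],
                        "transcript_id": [tx_ids[j] for j in cols_idx],
                        "role": [
                            "target" if tx_ids[j] in all_targets[iso_ids[i]] else "nontarget"
                            for i, j in zip(rows_idx, cols_idx)
                        ],
                        "rho": rho[rows_idx, cols_idx],
                        "p": p[rows_idx, cols_idx],
                        "fdr": fdr[rows_idx, cols_idx],
                    }
                )
            )

        group_rows = []
        for stratum in sorted(strata_sets):
            for i, iso in enumerate(iso_ids):
                tgt_idx = np.array(
                    [tx_pos[t] for t in strata_sets[stratum].get(iso, set())], dtype=int
                )
                nt_idx = np.array([tx_pos[t] for t in clean_nontargets[iso]], dtype=int)
                n_tar = int(np.isfinite(rho[i, tgt_idx]).sum()) if tgt_idx.size else 0
                n_nontar = int(np.isfinite(rho[i, nt_idx]).sum()) if nt_idx.size else 0
                if n_tar < 1 or n_nontar < 1:
                    _LOG.warning(
                        "isomiR %s, group %s, stratum %s: n_tar=%d, n_nontar=%d; skipped",
                        iso, group, stratum, n_tar, n_nontar,
                    )
                    continue
                m_tar = int(sig[i, tgt_idx].sum())
                m_nontar = int(sig[i, nt_idx].sum())
                adj = adjusted_ita(m_tar, n_tar, m_nontar, n_nontar)
                group_rows.append(
                    {
                        "isomir": iso,
                        "group": group,
                        "stratum": stratum,
                        "n_tar": n_tar,
                        "m_tar": m_tar,
                        "n_nontar": n_nontar,
                        "m_nontar": m_nontar,
                        "ita": m_tar,
                        "background_ita": background_ita(m_tar, n_tar, m_nontar, n_nontar),
                        "adjusted_ita": adj,
                        "adjusted_ita_signed_log": signed_log(adj),
                        "fisher_p": fisher_one_sided(m_tar, n_tar, m_nontar, n_nontar),
                        "fisher_fdr": np.nan,
                    }
                )
        gdf = pd.DataFrame(group_rows, columns=ITA_COLUMNS)
        for stratum, sub in gdf.groupby("stratum", sort=False):
            gdf.loc[sub.index, "fisher_fdr"] = bh_adjust(sub["fisher_p"])
        records.append(gdf)

    out = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=ITA_COLUMNS)
    )
    if return_correlations:
        corr = (
            pd.concat(corr_frames, ignore_index=True)
            if corr_frames
            else pd.DataFrame(columns=["group", "isomir", "transcript_id", "role", "rho", "p", "fdr"])
        )
        return out, corr
    return out
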