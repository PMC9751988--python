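"""Reading, unifying and comparing predicted-interaction tables.

Two TSV dialects are supported, mirroring the two target-prediction tools
the analysis consumes: an RNA22-like dialect (sites in any mRNA region, any
seed-binding type including the relaxed ``other`` category) and a
TargetScan-like dialect (classical seed types only, 3'-UTR only, 1-based
site coordinates).  Both are unified into a single interaction-table layout
with columns ``isomir, transcript_id, window_start, region, seed_type,
source``, 0-based half-open coordinates throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd

from .seed_model import CLASSICAL_SEED_TYPES, REGIONS, SEED_TYPES, classify_site

_LOG = logging.getLogger(__name__)

INTERACTION_COLUMNS = ["isomir", "transcript_id", "window_start", "region", "seed_type", "source"]
_SITE_KEY = ["isomir", "transcript_id", "window_start", "source"]

#: Default column maps for the two dialects (overridable per file).
RNA22_COLUMN_MAP = {
    "isomir": "mirna_id",
    "transcript_id": "transcript_id",
    "window_start": "site_start",
    "region": "region",
    "seed_type": "binding_type",
}
TARGETSCAN_COLUMN_MAP = {
    "isomir": "mirna_id",
    "transcript_id": "transcript_id",
    "window_start": "site_position",  # 1-based in file
    "seed_type": "seed_match",
}

#: Precedence used when a pair carries several site types (strongest first).
_SEED_TYPE_RANK = {t: i for i, t in enumerate(SEED_TYPES)}


def _validate_vocab(df: pd.DataFrame, path) -> None:
    bad_type = set(df["seed_type"].dropna()) - set(SEED_TYPES)
    if bad_type:
        raise ValueError(f"{path}: unknown seed types {sorted(bad_type)}; expected {SEED_TYPES}")
    bad_region = set(df["region"].dropna()) - set(REGIONS)
    if bad_region:
        raise ValueError(f"{path}: unknown regions {sorted(bad_region)}; expected {REGIONS}")


def _finish(df: pd.DataFrame, path, transcripts=None, isomir_seqs=None) -> pd.DataFrame:
    df = df.reindex(columns=INTERACTION_COLUMNS)
    df["window_start"] = df["window_start"].astype("Int64")
    if transcripts is not None:
        known = df["transcript_id"].isin(set(transcripts))
        dropped = int((~known).sum())
        if dropped:
            _LOG.info("%s: dropped %d rows with transcripts absent from the sequence set", path, dropped)
        df = df.loc[known]
        if isomir_seqs is not None:
            df = _reclassify(df, transcripts, isomir_seqs)
    before = len(df)
    df = df.drop_duplicates(subset=_SITE_KEY).reset_index(drop=True)
    if len(df) < before:
        _LOG.info("%s: removed %d duplicate rows", path, before - len(df))
    _validate_vocab(df, path)
    return df


def _reclassify(df: pd.DataFrame, transcripts, isomir_seqs) -> pd.DataFrame:
    """Re-derive seed types from sequence when both sides are available."""
    new_types = []
    for row in df.itertuples():
        iso = isomir_seqs.get(row.isomir)
        start = row.window_start
        if iso is None or pd.isna(start):
            new_types.append(row.seed_type)
            continue
        seq = transcripts[row.transcript_id].seq
        start = int(start)
        if start < 0 or start + 8 > len(seq):
            new_types.append(row.seed_type)
            continue
        observed = classify_site(iso, seq[start : start + 8])
        new_types.append(observed if observed is not None else row.seed_type)
    out = df.copy()
    out["seed_type"] = new_types
    return out


def read_rna22_table(path, column_map=None, transcripts=None, isomir_seqs=None) -> pd.DataFrame:
    """Read an RNA22-like prediction TSV into the unified layout.

    Sites carry 0-based coordinates, any region, and any seed type.  When
    ``transcripts`` (id -> TranscriptRecord) and ``isomir_seqs`` (id ->
    IsomiRSequence) are given, rows whose transcript is absent from the
    sequence set are dropped with a logged count and seed types are
    re-classified from sequence via :func:`~isoita.seed_model.classify_site`.
    """
    cmap = dict(RNA22_COLUMN_MAP, **(column_map or {}))
    raw = pd.read_csv(path, sep="\t", dtype={cmap["isomir"]: str, cmap["transcript_id"]: str})
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; expected RNA22-like schema "
            f"{sorted(cmap.values())}"
        )
    df = raw.rename(columns={v: k for k, v in cmap.items()})
    df["source"] = "RNA22"
    return _finish(df, path, transcripts, isomir_seqs)


def read_targetscan_table(path, column_map=None, transcripts=None, isomir_seqs=None) -> pd.DataFrame:
    """Read a TargetScan-like prediction TSV into the unified layout.

    The dialect admits only the four classical seed types, region is forced
    to 3'-UTR, and file coordinates are 1-based (converted to 0-based
    half-open on read).
    """
    cmap = dict(TARGETSCAN_COLUMN_MAP, **(column_map or {}))
    raw = pd.read_csv(path, sep="\t", dtype={cmap["isomir"]: str, cmap["transcript_id"]: str})
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; expected TargetScan-like schema "
            f"{sorted(cmap.values())}"
        )
    df = raw.rename(columns={v: k for k, v in cmap.items()})
    bad = set(df["seed_type"].dropna()) - set(CLASSICAL_SEED_TYPES)
    if bad:
        raise ValueError(
            f"{path}: seed types {sorted(bad)} are not allowed in the TargetScan "
            f"dialect (classical types only: {CLASSICAL_SEED_TYPES})"
        )
    df["window_start"] = df["window_start"].astype(int) - 1
    df["region"] = "3UTR"
    df["source"] = "TargetScan"
    return _finish(df, path, transcripts, isomir_seqs)


def write_rna22_table(table: pd.DataFrame, path, column_map=None) -> None:
    """Write the unified layout back out in the RNA22-like dialect."""
    cmap = dict(RNA22_COLUMN_MAP, **(column_map or {}))
    table.loc[table["source"] == "RNA22", list(cmap)].rename(columns=cmap).to_csv(
        path, sep="\t", index=False
    )


def write_targetscan_table(table: pd.DataFrame, path, column_map=None) -> None:
    """Write the unified layout back out in the TargetScan-like dialect (1-based)."""
    cmap = dict(TARGETSCAN_COLUMN_MAP, **(column_map or {}))
    out = table.loc[table["source"] == "TargetScan", list(cmap)].copy()
    out["window_start"] = out["window_start"].astype(int) + 1
    out.rename(columns=cmap).to_csv(path, sep="\t", index=False)


def union_interactions(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Union of two interaction tables.

    All site rows are retained (deduplicated on the site key) so stratified
    analyses see every annotation; pair-level views are obtained with
    :func:`interaction_pairs` / :func:`pair_level`.  The operation is
    commutative, associative and idempotent at pair level.
    """
    out = pd.concat([a, b], ignore_index=True).drop_duplicates(subset=_SITE_KEY)
    return out.reset_index(drop=True)


def interaction_pairs(table: pd.DataFrame) -> set:
    """The set of (isomir, transcript_id) pairs in a table."""
    return set(zip(table["isomir"], table["transcript_id"]))


def pair_level(table: pd.DataFrame) -> pd.DataFrame:
    """One row per (isomir, transcript) pair, labelled with the
    maximum-precedence seed type among its sites."""
    ranked = table.assign(_rank=table["seed_type"].map(_SEED_TYPE_RANK))
    idx = ranked.groupby(["isomir", "transcript_id"], sort=False)["_rank"].idxmin()
    return table.loc[idx.to_numpy()].reset_index(drop=True)


def jaccard(a: set, b: set) -> float:
    """Jaccard index |a & b| / |a | b|; defined as 0 when both sets are empty."""
    union = a | b
    if not union:
        _LOG.warning("jaccard of two empty sets; returning 0.0")
        return 0.0
    return len(a & b) / len(union)


@dataclass
class OverlapReport:
    """Overlap structure of named sets: exclusive regions, intersections, Jaccard."""

    names: list
    region_sizes: dict  # "A&B"-style exclusive-region pattern -> size
    intersection_sizes: dict  # pattern -> plain intersection size
    jaccard: dict  # "A|B" -> pairwise Jaccard
    union_size: int
    intersection_size: int

    def to_json_dict(self) -> dict:
        return {
            "names": self.names,
            "region_sizes": self.region_sizes,
            "intersection_sizes": self.intersection_sizes,
            "jaccard": self.jaccard,
            "union_size": self.union_size,
            "intersection_size": self.intersection_size,
        }


def compare_sets(sets: Mapping[str, set]) -> OverlapReport:
    """Venn-style overlap report for named sets (intended for up to 4 sets).

    ``region_sizes`` counts elements in exactly a given combination of sets
    (the exclusive Venn regions, which partition the union);
    ``intersection_sizes`` gives plain intersection sizes for every
    non-empty combination; ``jaccard`` holds every pairwise Jaccard index.
    """
    names = list(sets)
    if not names:
        raise ValueError("compare_sets requires at least one named set")
    sets = {n: set(s) for n, s in sets.items()}
    universe = set().union(*sets.values())

    region_sizes: dict = {}
    intersection_sizes: dict = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo))
            key = "&".join(combo)
            intersection_sizes[key] = len(inter)
            exclusive = inter - set().union(
                *(sets[n] for n in names if n not in combo), set()
            )
            region_sizes[key] = len(exclusive)

    jacc = {f"{a}|{b}": jaccard(sets[a], sets[b]) for a, b in combinations(names, 2)}
    return OverlapReport(
        names=names,
        region_sizes=region_sizes,
        intersection_sizes=intersection_sizes,
        jaccard=jacc,
        union_size=len(universe),
        intersection_size=len(set.intersection(*sets.values())) if sets else 0,
    )
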