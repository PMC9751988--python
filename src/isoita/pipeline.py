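"""End-to-end orchestration of the isomiR targeting-activity analysis.

The pipeline mirrors the analysis workflow: aggregate 3'-variants into
5'-isomiRs, normalize (median-of-ratios size factors, FPM for isomiRs,
FPKM for transcripts, log2(x+1)), select top-expressed isomiRs by median
coverage, drop low-expressed transcripts, unify prediction tables, compose
per-isomiR non-target sets via the 6-mer hash index, and compute ITA
records per sample group with active-set overlap reporting.

Every stage writes its TSV and logs its row counts; re-running on
identical inputs is byte-identical (there is no unseeded randomness
anywhere in the analysis path).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import expression, ita_stats, seed_model, target_io

_LOG = logging.getLogger(__name__)

_STAGES = ("correlations", "ita", "all")


class ConfigError(ValueError):
    """Invalid run configuration (maps to CLI exit code 2)."""


@dataclass
class RunConfig:
    """Paths and thresholds for one analysis run."""

    isomir_counts: str
    transcript_counts: str
    transcript_fasta: str
    regions: str
    isomir_seqs: str
    sample_groups: str
    outdir: str
    rna22: Optional[str] = None
    targetscan: Optional[str] = None
    rho_max: float = -0.3
    fdr_max: float = 0.05
    coverage: float = 0.99
    min_group_size: int = 100
    strata: Sequence[str] = ("pooled",)
    groups: Optional[Sequence[str]] = None  # restrict to these group labels
    per_group_normalization: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        if not -1 <= self.rho_max <= 0:
            raise ConfigError(f"rho_max must be in [-1, 0], got {self.rho_max}")
        if not 0 < self.fdr_max < 1:
            raise ConfigError(f"fdr_max must be in (0, 1), got {self.fdr_max}")
        if not 0 < self.coverage <= 1:
            raise ConfigError(f"coverage must be in (0, 1], got {self.coverage}")
        if self.min_group_size < 1:
            raise ConfigError("min_group_size must be >= 1")
        for mode in self.strata:
            if mode not in ("pooled", "seed_type", "region"):
                raise ConfigError(f"unknown stratum mode {mode!r}")
        if self.rna22 is None and self.targetscan is None:
            raise ConfigError("at least one prediction table (rna22/targetscan) is required")
        for name in ("isomir_counts", "transcript_counts", "transcript_fasta",
                     "regions", "isomir_seqs", "sample_groups", "rna22", "targetscan"):
            value = getattr(self, name)
            if value is not None and not Path(value).is_file():
                raise ConfigError(f"{name}: file not found: {value}")


def _normalize(counts, groups, mode, lengths, per_group):
    """Size-factor-normalize; optionally per sample group."""
    if not per_group:
        factors = expression.size_factors_median_of_ratios(counts)
        return expression.normalize(counts, factors, mode=mode, lengths=lengths)
    pieces = []
    for g in pd.unique(groups):
        cols = groups.index[groups == g]
        cols = [c for c in cols if c in counts.columns]
        sub = counts[cols]
        factors = expression.size_factors_median_of_ratios(sub)
        pieces.append(expression.normalize(sub, factors, mode=mode, lengths=lengths).data)
    data = pd.concat(pieces, axis=1)[counts.columns]
    return expression.NormalizedMatrix(data, mode)


def run_pipeline(cfg: RunConfig, until: str = "all") -> dict:
    """Execute the analysis and write the output bundle into ``cfg.outdir``.

    ``until`` stops early after ``"correlations"`` or ``"ita"``.  Returns a
    dict of in-memory results (ita table, correlation tables, active sets,
    overlap report) for programmatic use.
    """
    if until not in _STAGES:
        raise ConfigError(f"unknown stage {until!r}; expected one of {_STAGES}")
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- load
    iso_raw = expression.read_count_matrix(cfg.isomir_counts)
    tx_counts = expression.read_count_matrix(cfg.transcript_counts)
    groups = expression.read_sample_groups(cfg.sample_groups)
    if cfg.groups is not None:
        groups = groups[groups.isin(set(cfg.groups))]
    transcripts = seed_model.read_transcripts(cfg.transcript_fasta, cfg.regions)
    isomir_seqs = seed_model.read_isomir_sequences(cfg.isomir_seqs)
    _LOG.info(
        "loaded %d isomiR rows, %d transcripts, %d samples, %d groups",
        len(iso_raw), len(tx_counts), len(groups), groups.nunique(),
    )
    samples = [s for s in iso_raw.columns if s in set(tx_counts.columns) and s in groups.index]
    if not samples:
        raise ConfigError("no samples shared by both count matrices and the group map")
    iso_raw, tx_counts = iso_raw[samples], tx_counts[samples]
    groups = groups.loc[samples]

    # --- aggregate 3'-variants into 5'-isomiRs
    iso_counts = expression.aggregate_5prime_isomirs(iso_raw)
    _LOG.info("aggregated %d isomiR rows into %d 5'-isomiRs", len(iso_raw), len(iso_counts))
    iso_counts.to_csv(outdir / "aggregated_isomir_counts.tsv", sep="\t")

    # --- normalize (FPM isomiRs; FPKM transcripts) and log-transform
    lengths = pd.Series({tid: len(t) for tid, t in transcripts.items()}, name="length")
    missing_seq = [t for t in tx_counts.index if t not in lengths.index]
    if missing_seq:
        _LOG.info("dropping %d transcripts without sequence records", len(missing_seq))
        tx_counts = tx_counts.drop(index=missing_seq)
    iso_fpm = _normalize(iso_counts, groups, "FPM", None, cfg.per_group_normalization)
    tx_fpkm = _normalize(tx_counts, groups, "FPKM", lengths, cfg.per_group_normalization)

    # --- isomiR selection by median coverage; transcript zero filter
    medians = iso_fpm.data.median(axis=1)
    selected = expression.select_top_isomirs(medians, coverage=cfg.coverage)
    selected = [i for i in selected if i in isomir_seqs]
    _LOG.info("selected %d of %d 5'-isomiRs at %.2f median coverage",
              len(selected), len(iso_counts), cfg.coverage)
    medians.loc[selected].rename("median_fpm").rename_axis("isomir").reset_index().to_csv(
        outdir / "selected_isomirs.tsv", sep="\t", index=False
    )
    tx_kept = expression.filter_low_transcripts(tx_counts)
    _LOG.info("retained %d of %d transcripts after the zero filter", len(tx_kept), len(tx_counts))

    iso_log = iso_fpm.log_transform().data.loc[selected]
    tx_log = tx_fpkm.log_transform().data.loc[tx_kept.index]

    # --- prediction tables
    tables = []
    if cfg.rna22:
        tables.append(target_io.read_rna22_table(cfg.rna22, transcripts=transcripts,
                                                 isomir_seqs=isomir_seqs))
    if cfg.targetscan:
        tables.append(target_io.read_targetscan_table(cfg.targetscan, transcripts=transcripts,
                                                      isomir_seqs=isomir_seqs))
    interactions = tables[0]
    for extra in tables[1:]:
        interactions = target_io.union_interactions(interactions, extra)
    interactions = interactions[
        interactions["isomir"].isin(set(selected))
        & interactions["transcript_id"].isin(set(tx_kept.index))
    ].reset_index(drop=True)
    _LOG.info("interaction union: %d site rows, %d pairs",
              len(interactions), len(target_io.interaction_pairs(interactions)))
    interactions.to_csv(outdir / "interactions_union.tsv", sep="\t", index=False)

    # --- non-target sets over the retained transcriptome
    kept_records = [transcripts[t] for t in tx_kept.index]
    index = seed_model.build_kmer_index(kept_records, k=6)
    nontargets = {
        iso: seed_model.compose_nontarget_set(isomir_seqs[iso], index) for iso in selected
    }
    pd.DataFrame(
        [(iso, t) for iso, s in nontargets.items() for t in sorted(s)],
        columns=["isomir", "transcript_id"],
    ).to_csv(outdir / "nontarget_sets.tsv", sep="\t", index=False)
    _LOG.info("non-target sets: median size %d",
              int(np.median([len(s) for s in nontargets.values()])) if nontargets else 0)

    # --- correlations + ITA
    ita, corr = ita_stats.compute_ita_profile(
        iso_log, tx_log, groups, interactions, nontargets,
        strata=tuple(cfg.strata), rho_max=cfg.rho_max, fdr_max=cfg.fdr_max,
        min_group_size=cfg.min_group_size, return_correlations=True,
    )
    for g, sub in corr.groupby("group", sort=False):
        sub.to_csv(outdir / f"correlations_{g}.tsv", sep="\t", index=False)
    result = {"interactions": interactions, "nontargets": nontargets, "correlations": corr}
    if until == "correlations":
        return result

    ita.to_csv(outdir / "ita.tsv", sep="\t", index=False)
    _LOG.info("ITA table: %d records over %d groups", len(ita), ita["group"].nunique())
    result["ita"] = ita
    if until == "ita":
        return result

    # --- active sets and overlap report
    membership, report = report_active_sets(ita, fdr_max=cfg.fdr_max)
    membership.to_csv(outdir / "active_sets.tsv", sep="\t", index=False)
    if report is not None:
        with open(outdir / "overlap_report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2)
    result["active_sets"] = membership
    result["overlap_report"] = report
    return result


def report_active_sets(ita: pd.DataFrame, fdr_max: float = 0.05, stratum: str = "all"):
    """Per-group active 5'-isomiR sets and their overlap structure.

    An isomiR is *active* in a group when its Fisher FDR is below
    ``fdr_max`` in the given stratum.  Returns ``(membership, report)``
    where ``membership`` is a long table (isomir, group, active) and
    ``report`` an :class:`~isoita.target_io.OverlapReport` with all
    intersection-region sizes and pairwise Jaccard indices (``None`` when
    fewer than two groups are present).
    """
    sub = ita[ita["stratum"] == stratum]
    if sub.empty:
        raise ValueError(f"no ITA records in stratum {stratum!r}")
    membership = sub.assign(active=sub["fisher_fdr"] < fdr_max)[
        ["isomir", "group", "active"]
    ].reset_index(drop=True)
    groups = list(pd.unique(sub["group"]))
    active_sets = {
        g: set(sub.loc[(sub["group"] == g) & (sub["fisher_fdr"] < fdr_max), "isomir"])
        for g in groups
    }
    report = target_io.compare_sets(active_sets) if len(groups) >= 2 else None
    return membership, report
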