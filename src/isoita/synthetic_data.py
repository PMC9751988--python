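"""Self-contained synthetic inputs with the statistical structure the
isomiR-targeting analysis assumes.

The generator emulates the shape of the real inputs — isomiR and transcript
count tables over grouped samples, transcript sequences with region
boundaries, and prediction tables in both supported dialects — while
planting a known regulatory structure:

* a subset of isomiRs is *active*: each represses a block of designated
  target transcripts through a planted seed site (log-linear slope ``beta``
  on the log2 scale, so repression is monotone and Spearman-detectable);
* each isomiR owns a block of designated *non-target* transcripts scrubbed
  of every wobble-admissible seed 6-mer by rejection sampling;
* optionally, *confounded* isomiRs share a latent confounder (a hub-TF
  stand-in) with a fraction ``confounded_fraction`` of non-planted
  transcripts, creating anti-correlation without targeting — the scenario
  the background-ITA adjustment exists to neutralise;
* expression is log-normal: counts are ``round(2**value)`` of Gaussian
  log2-values, so zeros arise naturally at low baselines.

Every output is a pure function of :class:`SimulationConfig` (seed
included).  Ground truth is written for tests only; the analysis pipeline
never reads it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .seed_model import (
    WC_PARTNER,
    IsomiRId,
    IsomiRSequence,
    TranscriptRecord,
    build_kmer_index,
    classify_site,
    compose_nontarget_set,
    extract_seed,
    find_candidate_sites,
    reverse_complement,
    seed_site_kmers,
)
from . import target_io

_LOG = logging.getLogger(__name__)

_NTS = np.array(list("ACGU"))

ROLE_TRUE_TARGET = "true_target"
ROLE_CHANCE_SITE = "chance_site"
ROLE_INDEPENDENT_NONTARGET = "independent_nontarget"
ROLE_CONFOUNDED_NONTARGET = "confounded_nontarget"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the reference desk-scale experiment: 20 highly
    expressed 5'-isomiRs of which 10 actively repress 30 planted targets
    each (``beta = -1`` on the log2 scale), 200 samples per group, and no
    confounding.  ``confounded_fraction > 0`` switches on the hub-TF
    confounder for ``n_confounded`` otherwise-inactive isomiRs.
    """

    n_transcripts: int = 800
    transcript_length: tuple = (150, 500)
    n_isomirs: int = 20
    isomir_length: int = 22
    n_active: int = 10
    targets_per_isomir: int = 30
    nontargets_per_isomir: int = 20
    n_silent_transcripts: int = 10
    beta: float = -1.0                 # log2-scale slope of target on isomiR (<= 0)
    noise_sd: float = 0.5              # transcript log2 noise sd
    isomir_sd: float = 1.0             # isomiR log2 sd around its baseline
    isomir_mu_range: tuple = (8.0, 10.0)   # log2 baselines (post-selection regime)
    baseline_range: tuple = (1.0, 9.0)     # transcript log2 baselines
    silent_baseline: float = -3.0
    confounded_fraction: float = 0.0   # gamma: fraction of non-planted transcripts per confounder
    confounder_slope: float = 1.0
    n_confounded: int = 5              # confounded isomiRs (only when gamma > 0)
    n_samples_per_group: int = 200
    group_labels: tuple = ("LumA", "Normal")
    active_isomirs_by_group: Optional[Mapping[str, Sequence[int]]] = None
    planted_seed_type: str = "8mer"
    planted_region: str = "3UTR"
    n_3p_variants: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta > 0:
            raise ValueError("beta must be <= 0 (planted repression)")
        if min(self.n_transcripts, self.n_isomirs, self.n_samples_per_group) < 1:
            raise ValueError("all counts must be >= 1")
        needed = (
            self.n_active * self.targets_per_isomir
            + self.n_isomirs * self.nontargets_per_isomir
            + self.n_silent_transcripts
        )
        if needed > self.n_transcripts:
            raise ValueError(
                f"n_transcripts={self.n_transcripts} too small for "
                f"{needed} designated transcripts"
            )
        if not 0 <= self.confounded_fraction < 1:
            raise ValueError("confounded_fraction must be in [0, 1)")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("transcript_length", "group_labels", "isomir_mu_range", "baseline_range"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset (test-only; never read by the pipeline)."""

    sites: pd.DataFrame          # isomir, transcript_id, window_start, seed_type, region
    roles: pd.DataFrame          # isomir, transcript_id, role
    confounded: dict             # isomiR id -> list of confounded transcript ids
    isomirs: list                # IsomiRSequence, generation order
    planted_targets: dict        # isomiR id -> list of planted transcript ids

    @property
    def active_isomirs(self) -> list:
        return sorted(self.planted_targets)


def _random_seq(rng: np.random.Generator, length: int) -> list:
    return list(_NTS[rng.integers(0, 4, size=length)])


def _draw_isomirs(cfg: SimulationConfig, rng: np.random.Generator) -> list:
    """Random isomiR sequences with pairwise-distinct 6-nt seeds."""
    shifts = (0, 1, -1)
    isomirs, seeds_seen = [], set()
    for i in range(cfg.n_isomirs):
        while True:
            seq = "".join(_random_seq(rng, cfg.isomir_length))
            if seq[1:7] not in seeds_seen:
                seeds_seen.add(seq[1:7])
                break
        iso_id = IsomiRId(f"syn-miR-{i + 1:03d}-5p", shifts[i % len(shifts)])
        isomirs.append(IsomiRSequence(iso_id, seq))
    return isomirs


def build_site_window(iso: IsomiRSequence, seed_type: str, rng: np.random.Generator) -> str:
    """Construct an 8-nt mRNA window classifying exactly as ``seed_type``."""
    seed7 = iso.seq[1:8]
    rc7 = reverse_complement(seed7)       # opposes positions 8..2
    rc6 = reverse_complement(iso.seq[1:7])  # opposes positions 7..2
    non_wc8 = [c for c in "ACGU" if c != WC_PARTNER[seed7[6]]]
    if seed_type == "8mer":
        window = rc7 + "A"
    elif seed_type == "7mer-m8":
        window = rc7 + str(rng.choice([c for c in "CGU"]))
    elif seed_type == "7mer-A1":
        window = str(rng.choice(non_wc8)) + rc6 + "A"
    elif seed_type == "6mer":
        window = str(rng.choice(non_wc8)) + rc6 + str(rng.choice([c for c in "CGU"]))
    else:
        raise ValueError(f"cannot plant seed type {seed_type!r}")
    observed = classify_site(iso, window)
    if observed != seed_type:
        raise AssertionError(f"planted window classifies as {observed}, wanted {seed_type}")
    return window


def _region_bounds(length: int) -> tuple:
    return int(round(0.15 * length)), int(round(0.70 * length))


def _scrub_admissible(seq: list, kmers: set, rng: np.random.Generator, max_iter: int = 500) -> list:
    """Rejection-resample windows until no admissible 6-mer remains."""
    for _ in range(max_iter):
        joined = "".join(seq)
        hit = next(
            (p for p in range(len(joined) - 5) if joined[p : p + 6] in kmers), None
        )
        if hit is None:
            return seq
        seq[hit : hit + 6] = _random_seq(rng, 6)
    raise RuntimeError(
        "rejection sampling failed to remove all admissible 6-mers; "
        "try shorter transcripts or a less wobble-rich seed"
    )


def generate_transcriptome(cfg: SimulationConfig) -> tuple:
    """Generate transcripts, isomiRs, and the planted ground truth.

    Returns ``(transcripts, isomirs, truth)`` where ``transcripts`` is a
    list of :class:`TranscriptRecord`.  Active isomiRs are the first
    ``n_active``; each receives a disjoint block of target transcripts with
    one planted site of the requested type inside the requested region, and
    every isomiR receives a block of designated non-target transcripts
    scrubbed of its admissible 6-mers.  Roles are then assigned per
    (isomiR, transcript) pair by scanning the finished transcriptome, so
    chance seed sites on undesignated transcripts are labelled too.
    """
    rng = np.random.default_rng(cfg.seed)
    isomirs = _draw_isomirs(cfg, rng)
    active = isomirs[: cfg.n_active]

    lo, hi = cfg.transcript_length
    lengths = rng.integers(lo, hi + 1, size=cfg.n_transcripts)
    seqs = [_random_seq(rng, int(L)) for L in lengths]
    tx_ids = [f"TX{i:04d}" for i in range(cfg.n_transcripts)]

    planted_targets: dict = {str(iso.id): [] for iso in active}
    planted_sites = []
    cursor = 0
    for iso in active:
        for _ in range(cfg.targets_per_isomir):
            idx = cursor
            cursor += 1
            length = int(lengths[idx])
            utr5_end, cds_end = _region_bounds(length)
            window = build_site_window(iso, cfg.planted_seed_type, rng)
            region_span = {
                "5UTR": (0, utr5_end),
                "CDS": (utr5_end, cds_end),
                "3UTR": (cds_end, length),
            }[cfg.planted_region]
            # keep a full 8-nt window away from transcript ends
            start_lo = max(region_span[0], 1)
            start_hi = min(region_span[1], length - 9)
            if start_hi <= start_lo:
                raise ValueError(
                    f"region {cfg.planted_region} of transcript length {length} "
                    "too short to host a planted site"
                )
            start = int(rng.integers(start_lo, start_hi))
            seqs[idx][start : start + 8] = list(window)
            planted_targets[str(iso.id)].append(tx_ids[idx])
            planted_sites.append(
                {
                    "isomir": str(iso.id),
                    "transcript_id": tx_ids[idx],
                    "window_start": start,
                    "seed_type": cfg.planted_seed_type,
                    "region": cfg.planted_region,
                }
            )

    designated_clean: dict = {}
    for iso in isomirs:
        kmers = seed_site_kmers(extract_seed(iso), allow_wobble=True)
        block = []
        for _ in range(cfg.nontargets_per_isomir):
            idx = cursor
            cursor += 1
            seqs[idx] = _scrub_admissible(seqs[idx], kmers, rng)
            block.append(tx_ids[idx])
        designated_clean[str(iso.id)] = block

    silent_ids = set(tx_ids[cfg.n_transcripts - cfg.n_silent_transcripts :])

    transcripts = []
    for i, tid in enumerate(tx_ids):
        utr5_end, cds_end = _region_bounds(int(lengths[i]))
        transcripts.append(
            TranscriptRecord(tid, "".join(seqs[i]), utr5_end, cds_end)
        )

    # Confounded designation: each confounded isomiR's confounder drives a
    # gamma-fraction of non-planted transcripts (hub-TF mechanism).
    confounded: dict = {}
    if cfg.confounded_fraction > 0 and cfg.n_confounded > 0:
        planted_any = {t for block in planted_targets.values() for t in block}
        pool = [t for t in tx_ids if t not in planted_any and t not in silent_ids]
        conf_isos = isomirs[cfg.n_active : cfg.n_active + cfg.n_confounded]
        n_pick = int(round(cfg.confounded_fraction * len(pool)))
        for iso in conf_isos:
            confounded[str(iso.id)] = sorted(
                rng.choice(pool, size=n_pick, replace=False).tolist()
            )

    truth = GroundTruth(
        sites=pd.DataFrame(
            planted_sites,
            columns=["isomir", "transcript_id", "window_start", "seed_type", "region"],
        ),
        roles=_assign_roles(isomirs, transcripts, planted_targets, confounded),
        confounded=confounded,
        isomirs=isomirs,
        planted_targets=planted_targets,
    )
    return transcripts, isomirs, truth


def _assign_roles(isomirs, transcripts, planted_targets, confounded) -> pd.DataFrame:
    index = build_kmer_index(transcripts, k=6)
    rows = []
    for iso in isomirs:
        iso_id = str(iso.id)
        planted = set(planted_targets.get(iso_id, ()))
        nontar = compose_nontarget_set(iso, index)
        conf = set(confounded.get(iso_id, ()))
        # chance_site covers transcripts carrying an admissible 6-mer; a
        # 6-mer at a transcript edge with no full 8-nt window still excludes
        # the transcript from the non-target set, which is the conservative
        # choice for a negative control.
        for t in index.transcript_ids:
            if t in planted:
                role = ROLE_TRUE_TARGET
            elif t in nontar:
                role = ROLE_CONFOUNDED_NONTARGET if t in conf else ROLE_INDEPENDENT_NONTARGET
            else:
                role = ROLE_CHANCE_SITE
            rows.append((iso_id, t, role))
    df = pd.DataFrame(rows, columns=["isomir", "transcript_id", "role"])
    return df.sort_values(["isomir", "transcript_id"], ignore_index=True)


def generate_expression(cfg: SimulationConfig, truth: GroundTruth) -> tuple:
    """Simulate grouped count matrices consistent with the planted truth.

    Returns ``(isomir_variant_counts, transcript_counts, groups)``.  IsomiR
    counts are split across ``n_3p_variants`` 3'-end variants (rows
    ``"name|shift|v<k>"``) whose proportions are fixed per isomiR, so
    5'-aggregation can be exercised downstream.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    isomirs = truth.isomirs
    n_iso = len(isomirs)
    iso_ids = [str(iso.id) for iso in isomirs]
    tx_ids = sorted(set(truth.roles["transcript_id"]))
    n_tx = len(tx_ids)
    tx_pos = {t: i for i, t in enumerate(tx_ids)}

    mu = rng.uniform(*cfg.isomir_mu_range, size=n_iso)
    baselines = rng.uniform(*cfg.baseline_range, size=n_tx)
    silent = [t for t in tx_ids if int(t[2:]) >= cfg.n_transcripts - cfg.n_silent_transcripts]
    for t in silent:
        baselines[tx_pos[t]] = cfg.silent_baseline

    active_by_group = {}
    default_active = list(range(min(cfg.n_active, n_iso)))
    for g in cfg.group_labels:
        if cfg.active_isomirs_by_group is not None:
            active_by_group[g] = list(cfg.active_isomirs_by_group.get(g, ()))
        else:
            active_by_group[g] = default_active

    sample_ids, sample_groups = [], []
    iso_blocks, tx_blocks = [], []
    for g in cfg.group_labels:
        n = cfg.n_samples_per_group
        ids = [f"S-{g}-{j:04d}" for j in range(n)]
        sample_ids += ids
        sample_groups += [g] * n

        iso_log = mu[:, None] + rng.normal(0.0, cfg.isomir_sd, size=(n_iso, n))
        conf_z = {}
        for c_id in truth.confounded:
            z = rng.normal(0.0, 1.0, size=n)
            conf_z[c_id] = z
            iso_log[iso_ids.index(c_id)] += cfg.confounder_slope * z

        tx_log = baselines[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_tx, n))
        for k in active_by_group[g]:
            iso_id = iso_ids[k]
            for t in truth.planted_targets.get(iso_id, ()):
                tx_log[tx_pos[t]] += cfg.beta * (iso_log[k] - mu[k])
        for c_id, targets in truth.confounded.items():
            for t in targets:
                tx_log[tx_pos[t]] -= cfg.confounder_slope * conf_z[c_id]

        iso_blocks.append(iso_log)
        tx_blocks.append(tx_log)

    iso_counts = np.rint(np.exp2(np.concatenate(iso_blocks, axis=1))).astype(np.int64)
    tx_counts = np.rint(np.exp2(np.concatenate(tx_blocks, axis=1))).astype(np.int64)

    # Fixed per-isomiR 3'-variant proportions; per-cell multinomial split.
    props = rng.dirichlet(np.full(cfg.n_3p_variants, 5.0), size=n_iso)
    variant_rows, variant_ids = [], []
    for i, iso_id in enumerate(iso_ids):
        split = rng.multinomial(iso_counts[i], props[i])
        for k in range(cfg.n_3p_variants):
            variant_ids.append(f"{iso_id}|v{k + 1}")
            variant_rows.append(split[:, k])

    iso_df = pd.DataFrame(variant_rows, index=pd.Index(variant_ids, name="isomir"), columns=sample_ids)
    tx_df = pd.DataFrame(tx_counts, index=pd.Index(tx_ids, name="transcript_id"), columns=sample_ids)
    groups = pd.Series(sample_groups, index=pd.Index(sample_ids, name="sample_id"), name="group")
    return iso_df, tx_df, groups


def predict_sites(
    transcripts: Sequence[TranscriptRecord],
    isomirs: Sequence[IsomiRSequence],
    seed_types: Sequence[str] = target_io.CLASSICAL_SEED_TYPES,
) -> pd.DataFrame:
    """Internal sequence-based predictor over index-discoverable sites.

    Returns the unified interaction layout with ``source = "internal"``.
    By default only the four classical seed types are emitted: in uniform
    random sequence the relaxed ``other`` motif occurs at a high chance
    rate (real prediction tools prune such sites with energy and pattern
    filters that are out of scope here), so emitting it would swamp the
    predicted-target sets with background.  Pass
    ``seed_types=SEED_TYPES`` to include ``other`` sites as well.
    """
    index = build_kmer_index(transcripts, k=6)
    tmap = {t.transcript_id: t for t in transcripts}
    wanted = set(seed_types)
    rows = []
    for iso in isomirs:
        for s in find_candidate_sites(iso, tmap, index):
            if s.seed_type not in wanted:
                continue
            rows.append((s.isomir, s.transcript_id, s.window_start, s.region, s.seed_type, "internal"))
    return pd.DataFrame(rows, columns=target_io.INTERACTION_COLUMNS)


def write_fixture_bundle(cfg: SimulationConfig, outdir) -> dict:
    """Generate a dataset and write the full input bundle to ``outdir``.

    Files: transcript FASTA + region TSV, isomiR sequence TSV, isomiR
    (3'-variant level) and transcript count TSVs, sample-group TSV,
    RNA22-like and TargetScan-like prediction TSVs (the internal
    predictor's output reformatted into each dialect), ground-truth TSVs,
    and the simulation config as JSON.  Returns a dict of paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, isomirs, truth = generate_transcriptome(cfg)
    iso_counts, tx_counts, groups = generate_expression(cfg, truth)
    sites = predict_sites(transcripts, isomirs)

    paths = {name: outdir / fname for name, fname in [
        ("transcript_fasta", "transcripts.fasta"),
        ("regions", "regions.tsv"),
        ("isomir_seqs", "isomir_seqs.tsv"),
        ("isomir_counts", "isomir_counts.tsv"),
        ("transcript_counts", "transcript_counts.tsv"),
        ("sample_groups", "sample_groups.tsv"),
        ("rna22", "rna22_like.tsv"),
        ("targetscan", "targetscan_like.tsv"),
        ("ground_truth_roles", "ground_truth_roles.tsv"),
        ("ground_truth_sites", "ground_truth_sites.tsv"),
        ("config", "sim_config.json"),
    ]}

    with open(paths["transcript_fasta"], "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n{t.seq}\n")
    pd.DataFrame(
        [(t.transcript_id, t.utr5_end, t.cds_end) for t in transcripts],
        columns=["transcript_id", "utr5_end", "cds_end"],
    ).to_csv(paths["regions"], sep="\t", index=False)
    pd.DataFrame(
        [(str(iso.id), iso.seq) for iso in isomirs], columns=["isomir", "sequence"]
    ).to_csv(paths["isomir_seqs"], sep="\t", index=False)
    iso_counts.to_csv(paths["isomir_counts"], sep="\t")
    tx_counts.to_csv(paths["transcript_counts"], sep="\t")
    groups.rename("group").rename_axis("sample_id").reset_index().to_csv(
        paths["sample_groups"], sep="\t", index=False
    )

    rna22 = sites.assign(source="RNA22")
    target_io.write_rna22_table(rna22, paths["rna22"])
    ts = sites[
        sites["seed_type"].isin(target_io.CLASSICAL_SEED_TYPES) & (sites["region"] == "3UTR")
    ].assign(source="TargetScan")
    target_io.write_targetscan_table(ts, paths["targetscan"])

    truth.roles.to_csv(paths["ground_truth_roles"], sep="\t", index=False)
    truth.sites.to_csv(paths["ground_truth_sites"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        cfg_dict = dataclasses.asdict(cfg)
        if cfg_dict.get("active_isomirs_by_group") is not None:
            cfg_dict["active_isomirs_by_group"] = {
                k: list(v) for k, v in cfg_dict["active_isomirs_by_group"].items()
            }
        json.dump(cfg_dict, fh, indent=2, default=list)
    return {k: str(v) for k, v in paths.items()}
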