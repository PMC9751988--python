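"""IsomiR identity, seed extraction, and wobble-aware seed-site matching.

A mature miRNA recognises its targets mainly through its *seed region*,
nucleotides 2-7 (extended seed: 2-8) counted from the miRNA 5' end.  5'-end
isoforms (5'-isomiRs) shift this window, so every 5'-isomiR carries its own
seed and hence its own targetome.  This module provides:

* :class:`IsomiRId` / :class:`IsomiRSequence` — the ``name|shift`` notation
  for 5'-isomiRs and their RNA sequences;
* seed-site matching under Watson-Crick pairing with optional G:U wobbles,
  via the admissible-k-mer construction (:func:`seed_site_kmers`);
* classification of 8-nt mRNA windows into the canonical seed-site types
  (8mer, 7mer-m8, 7mer-A1, 6mer) plus a relaxed ``other`` category that
  allows unlimited wobbles and at most one mismatch or bulged nucleotide
  (:func:`classify_site`);
* a 6-mer hash index over a transcriptome (:func:`build_kmer_index`) and the
  composition of per-isomiR *non-target* sets — transcripts containing no
  wobble-tolerant seed-binding 6-mer anywhere in their sequence
  (:func:`compose_nontarget_set`).  Non-targets serve as negative controls
  for correlation-based target filtering.

Coordinates are 0-based, half-open throughout.  Input sequences written in
the DNA alphabet are transcribed (T -> U) and upper-cased at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

_LOG = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick partner of a miRNA nucleotide on the mRNA strand.
WC_PARTNER: Mapping[str, str] = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Admissible mRNA partners of a miRNA nucleotide when G:U wobbles are
#: allowed (both G(miRNA):U(mRNA) and U(miRNA):G(mRNA) orientations count).
WOBBLE_PARTNERS: Mapping[str, frozenset] = {
    "A": frozenset("U"),
    "C": frozenset("G"),
    "G": frozenset("CU"),
    "U": frozenset("AG"),
}

SEED_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "other")
CLASSICAL_SEED_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
REGIONS = ("5UTR", "CDS", "3UTR")


class InvalidSequenceError(ValueError):
    """A sequence violates the RNA alphabet or a length precondition."""


def canonicalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Upper-case ``seq`` and transcribe T->U; reject non-RNA characters."""
    s = str(seq).upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"{context} contains non-RNA characters {sorted(bad)}: {seq!r}"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an RNA string (5'->3' in, 5'->3' out)."""
    return "".join(WC_PARTNER[c] for c in reversed(seq))


@dataclass(frozen=True, order=True)
class IsomiRId:
    """Identity of a 5'-isomiR: a miRNA name plus a signed 5'-end shift.

    The shift is counted in the 5'->3' direction: positive means the isomiR
    lacks that many nucleotides from the canonical 5' end, negative means it
    carries extra 5' nucleotides.  String form is ``"<name>|<signed shift>"``
    with an explicit ``+`` for positive shifts and ``|0`` for the canonical
    form, e.g. ``hsa-miR-192-5p|+1``.
    """

    mirna_name: str
    shift: int

    def __post_init__(self) -> None:
        if not self.mirna_name:
            raise ValueError("mirna_name must be non-empty")
        if "|" in self.mirna_name:
            raise ValueError(f"mirna_name may not contain '|': {self.mirna_name!r}")

    def __str__(self) -> str:
        return f"{self.mirna_name}|{self.shift:+d}" if self.shift else f"{self.mirna_name}|0"

    @classmethod
    def parse(cls, text: str) -> "IsomiRId":
        """Parse ``"name|shift"``; round-trips losslessly with ``str()``."""
        name, sep, shift = str(text).rpartition("|")
        if not sep or not name:
            raise ValueError(f"not a 'name|shift' isomiR id: {text!r}")
        try:
            return cls(name, int(shift))
        except ValueError as exc:
            raise ValueError(f"bad shift in isomiR id {text!r}") from exc


@dataclass(frozen=True)
class IsomiRSequence:
    """A 5'-isomiR and its 5'->3' RNA sequence.

    The sequence must be at least 8 nt so seed positions 1-8 exist; mature
    isomiRs are typically 16-30 nt.
    """

    id: IsomiRId
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", canonicalize_rna(self.seq, context=f"isomiR {self.id}"))
        if len(self.seq) < 8:
            raise InvalidSequenceError(
                f"isomiR {self.id} is {len(self.seq)} nt; at least 8 nt required "
                "(seed positions 1-8 must exist)"
            )


@dataclass(frozen=True)
class SeedMatchProfile:
    """Per-position admissible mRNA nucleotides for a seed under a pairing rule.

    ``admissible[i]`` is the set of mRNA nucleotides that may oppose seed
    position ``2 + i``.  Sets are singletons under Watson-Crick-only pairing
    and have size 1-2 when G:U wobbles are allowed.
    """

    seed: str
    allow_wobble: bool
    admissible: tuple = field(init=False)

    def __post_init__(self) -> None:
        seed = canonicalize_rna(self.seed, context="seed")
        object.__setattr__(self, "seed", seed)
        rule = WOBBLE_PARTNERS if self.allow_wobble else {k: frozenset(v) for k, v in WC_PARTNER.items()}
        object.__setattr__(self, "admissible", tuple(rule[c] for c in seed))


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with half-open region boundaries.

    Regions partition the sequence: 5'-UTR = ``[0, utr5_end)``, CDS =
    ``[utr5_end, cds_end)``, 3'-UTR = ``[cds_end, len)``.
    """

    transcript_id: str
    seq: str
    utr5_end: int
    cds_end: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "seq", canonicalize_rna(self.seq, context=f"transcript {self.transcript_id}")
        )
        if not (0 <= self.utr5_end <= self.cds_end <= len(self.seq)):
            raise ValueError(
                f"transcript {self.transcript_id}: need 0 <= utr5_end ({self.utr5_end}) "
                f"<= cds_end ({self.cds_end}) <= len ({len(self.seq)})"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SiteAnnotation:
    """One predicted seed-binding site on a transcript.

    ``window_start`` is the 0-based start of the 8-nt mRNA window (5'->3')
    whose 3'-most nucleotide opposes miRNA position 1.
    """

    transcript_id: str
    window_start: int
    seed_type: str
    region: str
    isomir: str = ""


def extract_seed(iso: "IsomiRSequence | str", extended: bool = False) -> str:
    """Return the seed: positions 2-7 (6 nt), or 2-8 (7 nt) if ``extended``.

    Positions are 1-based on the isomiR's own 5' end, i.e. after any
    5'-shift has been applied to the sequence.
    """
    seq = iso.seq if isinstance(iso, IsomiRSequence) else canonicalize_rna(iso, context="isomiR")
    if len(seq) < 8:
        raise InvalidSequenceError(f"isomiR sequence shorter than 8 nt: {seq!r}")
    return seq[1:8] if extended else seq[1:7]


def seed_site_kmers(seed: str, allow_wobble: bool) -> set:
    """All mRNA 6-mers (read 5'->3') that fully pair with a 6-nt seed.

    Pairing is antiparallel: the mRNA 6-mer's last nucleotide opposes seed
    position 2.  With ``allow_wobble=False`` the result is exactly the
    Watson-Crick reverse complement (a single 6-mer); with wobbles the set
    size is ``2**(#G + #U in the seed)``.
    """
    seed = canonicalize_rna(seed, context="seed")
    if len(seed) != 6:
        raise InvalidSequenceError(f"seed must be a 6-mer, got {len(seed)} nt: {seed!r}")
    if not allow_wobble:
        return {reverse_complement(seed)}
    profile = SeedMatchProfile(seed, allow_wobble=True)
    # mRNA k-mer read 5'->3' pairs with the seed read 3'->5'.
    return {"".join(chars) for chars in product(*reversed(profile.admissible))}


def _pairs_wobble(mi_nt: str, m_nt: str) -> bool:
    return m_nt in WOBBLE_PARTNERS[mi_nt]


def _relaxed_seed_pairing(seed6: str, window: str) -> bool:
    """Seed 2-7 pairing with unlimited wobbles and at most one irregularity.

    The single permitted irregularity is a mismatch (checked in register on
    ``window[1:7]``), one unpaired mRNA nucleotide (the 7-nt segment
    ``window[0:7]`` opposite seed 2-7, one deletion), or one unpaired seed
    nucleotide (the 5-nt mRNA core ``window[2:7]``, one seed deletion).
    """
    # In-register: seed position 2+j opposes window[6-j].
    mismatches = sum(not _pairs_wobble(seed6[j], window[6 - j]) for j in range(6))
    if mismatches <= 1:
        return True
    # One bulged mRNA nucleotide: delete one of the 7 mRNA positions.
    segment = window[:7]
    for d in range(7):
        m = segment[:d] + segment[d + 1:]
        if all(_pairs_wobble(seed6[j], m[5 - j]) for j in range(6)):
            return True
    # One bulged (unpaired) seed nucleotide: delete one of the 6 seed positions.
    core = window[2:7]
    for d in range(6):
        s = seed6[:d] + seed6[d + 1:]
        if all(_pairs_wobble(s[j], core[4 - j]) for j in range(5)):
            return True
    return False


def classify_site(iso: "IsomiRSequence | str", window: str) -> "str | None":
    """Classify an 8-nt mRNA window against an isomiR's seed.

    ``window`` is read 5'->3'; its 3'-most nucleotide opposes miRNA position
    1, so ``window[8 - p]`` opposes miRNA position ``p``.  Returns one of
    ``"8mer"``, ``"7mer-m8"``, ``"7mer-A1"``, ``"6mer"``, ``"other"`` or
    ``None``:

    * ``8mer`` — positions 2-8 Watson-Crick paired and an A opposite position 1;
    * ``7mer-m8`` — positions 2-8 WC paired, opposite-1 not A;
    * ``7mer-A1`` — positions 2-7 WC paired, position 8 not WC paired, opposite-1 A;
    * ``6mer`` — positions 2-7 WC paired, position 8 not WC paired, opposite-1 not A;
    * ``other`` — positions 2-7 pair completely under the relaxed rule
      (unlimited G:U wobbles plus at most one mismatch or bulged nucleotide)
      without being one of the classical types.

    Precedence is fixed: 8mer > 7mer-m8 > 7mer-A1 > 6mer > other.
    """
    seq = iso.seq if isinstance(iso, IsomiRSequence) else canonicalize_rna(iso, context="isomiR")
    if len(seq) < 8:
        raise InvalidSequenceError(f"isomiR sequence shorter than 8 nt: {seq!r}")
    window = canonicalize_rna(window, context="mRNA window")
    if len(window) != 8:
        raise InvalidSequenceError(f"window must be 8 nt, got {len(window)}: {window!r}")

    seed7 = seq[1:8]  # miRNA positions 2-8
    wc = [WC_PARTNER[seed7[p - 2]] == window[8 - p] for p in range(2, 9)]
    wc_2_7 = all(wc[:6])
    wc_8 = wc[6]
    a_opposite_1 = window[7] == "A"

    if wc_2_7 and wc_8:
        return "8mer" if a_opposite_1 else "7mer-m8"
    if wc_2_7:
        return "7mer-A1" if a_opposite_1 else "6mer"
    if _relaxed_seed_pairing(seq[1:7], window):
        return "other"
    return None


@dataclass
class KmerIndex:
    """Hash index mapping every k-mer to its (transcript_id, start) positions."""

    k: int
    positions: dict
    transcript_ids: frozenset

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.positions.values())


def build_kmer_index(transcripts: Sequence[TranscriptRecord], k: int) -> KmerIndex:
    """Index every k-mer occurrence in ``transcripts``.

    Total indexed positions equal ``sum(max(0, len - k + 1))``; transcripts
    shorter than ``k`` contribute nothing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    positions: dict = {}
    for t in transcripts:
        seq = t.seq
        for start in range(len(seq) - k + 1):
            positions.setdefault(seq[start : start + k], []).append((t.transcript_id, start))
    return KmerIndex(k=k, positions=positions, transcript_ids=frozenset(t.transcript_id for t in transcripts))


def compose_nontarget_set(iso: IsomiRSequence, index: KmerIndex) -> set:
    """Transcripts with zero wobble-tolerant seed-binding 6-mers for ``iso``.

    The admissible 6-mers are those of :func:`seed_site_kmers` on the 6-nt
    seed (positions 2-7) with unlimited G:U wobbles; the non-target set is
    the complement of the union of their posting lists over the full
    transcript sequences (all regions).  These transcripts serve as
    negative controls for the isomiR.
    """
    if index.k != 6:
        raise ValueError(f"non-target composition requires a 6-mer index, got k={index.k}")
    if not index.positions:
        _LOG.warning("compose_nontarget_set: empty k-mer index; returning empty set")
        return set()
    kmers = seed_site_kmers(extract_seed(iso), allow_wobble=True)
    hit = set()
    for kmer in kmers:
        hit.update(tid for tid, _ in index.positions.get(kmer, ()))
    return set(index.transcript_ids) - hit


def assign_region(t: TranscriptRecord, window_start: int) -> str:
    """Region label of a site keyed by its 5'-most mRNA position.

    Boundary-spanning sites take the region of their start position (the
    half-open partition makes this deterministic).
    """
    if not (0 <= window_start < len(t.seq)):
        raise ValueError(
            f"window_start {window_start} out of range for transcript "
            f"{t.transcript_id} of length {len(t.seq)}"
        )
    if window_start < t.utr5_end:
        return "5UTR"
    if window_start < t.cds_end:
        return "CDS"
    return "3UTR"


def find_candidate_sites(
    iso: IsomiRSequence,
    transcripts: Mapping[str, TranscriptRecord],
    index: KmerIndex,
) -> list:
    """Locate and classify seed-binding sites for one isomiR.

    Candidate positions are occurrences of any wobble-admissible 6-mer (the
    hash-index route); each candidate's enclosing 8-nt window is then
    classified with :func:`classify_site`.  Windows truncated by a
    transcript end are skipped.  Sites whose relaxed pairing relies on a
    mismatch or bulge without a fully wobble-paired 6-mer core are not
    discoverable by this scan.
    """
    sites = []
    iso_id = str(iso.id)
    for kmer in sorted(seed_site_kmers(extract_seed(iso), allow_wobble=True)):
        for tid, pos in index.positions.get(kmer, ()):
            t = transcripts[tid]
            start = pos - 1  # window[1:7] is the 6-mer core
            if start < 0 or start + 8 > len(t.seq):
                continue
            seed_type = classify_site(iso, t.seq[start : start + 8])
            if seed_type is None:
                continue
            sites.append(
                SiteAnnotation(
                    transcript_id=tid,
                    window_start=start,
                    seed_type=seed_type,
                    region=assign_region(t, start),
                    isomir=iso_id,
                )
            )
    sites.sort(key=lambda s: (s.transcript_id, s.window_start))
    return sites


# ---------------------------------------------------------------------------
# External interfaces: FASTA + region table readers, BED-like site output.

def read_transcripts(fasta_path, regions_path) -> dict:
    """Read transcripts from FASTA plus a region TSV.

    The FASTA id is the first whitespace-delimited token of the header; the
    region table has columns ``transcript_id``, ``utr5_end``, ``cds_end``
    (0-based half-open).  Returns ``{transcript_id: TranscriptRecord}``.
    """
    import pandas as pd
    from Bio import SeqIO

    regions = pd.read_csv(regions_path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "utr5_end", "cds_end"}
    if not required.issubset(regions.columns):
        raise ValueError(f"region table must have columns {sorted(required)}")
    bounds = regions.set_index("transcript_id")
    out = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in bounds.index:
            raise ValueError(f"transcript {rec.id} missing from region table")
        row = bounds.loc[rec.id]
        out[rec.id] = TranscriptRecord(
            transcript_id=rec.id,
            seq=str(rec.seq),
            utr5_end=int(row["utr5_end"]),
            cds_end=int(row["cds_end"]),
        )
    return out


def read_isomir_sequences(path) -> dict:
    """Read a two-column TSV (``isomir``, ``sequence``) of isomiR sequences."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"isomir", "sequence"}.issubset(df.columns):
        raise ValueError("isomiR sequence table must have columns ['isomir', 'sequence']")
    return {
        row.isomir: IsomiRSequence(IsomiRId.parse(row.isomir), row.sequence)
        for row in df.itertuples()
    }


def write_sites_bed(sites: Iterable[SiteAnnotation], path) -> None:
    """Write sites as BED-like TSV: transcript, window start/end, isomiR, type, region."""
    import pandas as pd

    rows = [
        (s.transcript_id, s.window_start, s.window_start + 8, s.isomir, s.seed_type, s.region)
        for s in sites
    ]
    pd.DataFrame(
        rows,
        columns=["transcript_id", "window_start", "window_end", "isomir", "seed_type", "region"],
    ).to_csv(path, sep="\t", index=False)
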