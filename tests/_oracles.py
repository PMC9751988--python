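"""Independent brute-force oracles used to validate the implementation.

Everything here is written directly from the definitions (per-position
pairing, exhaustive enumeration, integer arithmetic) and deliberately
avoids the code paths it is used to check.
"""

from __future__ import annotations

from math import comb

import numpy as np

WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
# admissible mRNA partners of a miRNA nucleotide, G:U wobbles in both orientations
WOBBLE = {"A": "U", "C": "G", "G": "CU", "U": "AG"}
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def pairs_wobble(mirna_nt: str, mrna_nt: str) -> bool:
    return mrna_nt in WOBBLE[mirna_nt]


def brute_force_seed_kmers(seed: str, allow_wobble: bool) -> set:
    """All pairing mRNA 6-mers by exhaustive enumeration over 4**6 candidates."""
    from itertools import product

    rule = WOBBLE if allow_wobble else WC
    out = set()
    for chars in product("ACGU", repeat=6):
        kmer = "".join(chars)
        # antiparallel: kmer[k] opposes seed position 7-k, i.e. seed[5-k]
        if all(kmer[k] in rule[seed[5 - k]] for k in range(6)):
            out.add(kmer)
    return out


def brute_force_nontargets(iso_seq: str, transcripts: dict) -> set:
    """Per-position pairing scan: transcripts with no wobble-paired seed window."""
    seed = iso_seq[1:7]
    out = set()
    for tid, seq in transcripts.items():
        hit = False
        for p in range(len(seq) - 5):
            if all(seq[p + k] in WOBBLE[seed[5 - k]] for k in range(6)):
                hit = True
                break
        if not hit:
            out.add(tid)
    return out


def brute_force_nontargets_np(iso_seq: str, coded_transcripts: dict) -> set:
    """Vectorised per-position pairing scan over integer-coded sequences."""
    seed = iso_seq[1:7]
    adm = np.zeros((6, 4), dtype=bool)
    for k in range(6):
        for nt, c in _CODE.items():
            adm[k, c] = nt in WOBBLE[seed[5 - k]]
    out = set()
    for tid, codes in coded_transcripts.items():
        L = len(codes)
        if L < 6:
            out.add(tid)
            continue
        ok = adm[0][codes[: L - 5]]
        for k in range(1, 6):
            ok &= adm[k][codes[k : L - 5 + k]]
        if not ok.any():
            out.add(tid)
    return out


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def classify_oracle(iso_seq: str, window: str):
    """Direct transcription of the seed-site motif definitions.

    ``opp[i]`` is the mRNA nucleotide opposite miRNA position ``i + 1``
    (the window reversed).
    """
    s = iso_seq
    opp = window[::-1]

    def wc(p: int) -> bool:
        return WC[s[p - 1]] == opp[p - 1]

    wc_2_8 = all(wc(p) for p in range(2, 9))
    wc_2_7 = all(wc(p) for p in range(2, 8))
    a1 = opp[0] == "A"
    if wc_2_8 and a1:
        return "8mer"
    if wc_2_8:
        return "7mer-m8"
    if wc_2_7 and not wc(8) and a1:
        return "7mer-A1"
    if wc_2_7 and not wc(8):
        return "6mer"

    seed6 = s[1:7]
    # wobbles free, at most one mismatch, in register
    if sum(0 if pairs_wobble(s[p - 1], opp[p - 1]) else 1 for p in range(2, 8)) <= 1:
        return "other"
    # one bulged mRNA nucleotide: 7 mRNA positions opposite seed 2-7
    segment = opp[1:8]
    for d in range(7):
        m = segment[:d] + segment[d + 1 :]
        if all(pairs_wobble(seed6[j], m[j]) for j in range(6)):
            return "other"
    # one bulged seed nucleotide: 5-nt mRNA core opposite positions 2-6
    core = opp[1:6]
    for d in range(6):
        sd = seed6[:d] + seed6[d + 1 :]
        if all(pairs_wobble(sd[j], core[j]) for j in range(5)):
            return "other"
    return None


def bh_oracle(pvals) -> list:
    """O(m^2) step-up definition: q_(i) = min_{j >= i} p_(j) * m / j, clipped."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    for rank in range(1, m + 1):
        i = order[rank - 1]
        adj[i] = min(
            1.0, min(pvals[order[r - 1]] * m / r for r in range(rank, m + 1))
        )
    return adj


def fisher_tail_oracle(m_tar: int, n_tar: int, m_nontar: int, n_nontar: int) -> float:
    """Exact hypergeometric tail P(X >= m_tar) via integer binomials."""
    N = n_tar + n_nontar
    K = m_tar + m_nontar
    n = n_tar
    lo = max(m_tar, 0)
    hi = min(K, n)
    numerator = sum(comb(K, x) * comb(N - K, n - x) for x in range(lo, hi + 1))
    return numerator / comb(N, n)


def midranks(values) -> list:
    """Mid-rank (average-rank) assignment with tie handling, by hand."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of mid-ranks, computed from first principles."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5
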