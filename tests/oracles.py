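"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (plain Python loops, no shared code
with the package implementation) so it can serve as ground truth for the
vectorized search, the ranking metrics, and the boosting recurrence.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_scan(genome, protospacer: str, max_mm: int, pam_pattern: str):
    """Both-strand sliding-window scan; returns a set of hit tuples.

    Each hit is (chrom, start, strand, site_seq, mismatch_positions) with
    0-based half-open forward-strand coordinates and site_seq on the
    matching strand.  Windows containing non-ACGT bases are skipped.
    """

    def pam_ok(p3):
        return all(p3[i] in _IUPAC[pam_pattern[i]] for i in range(3))

    hits = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        for start in range(len(seq) - 22):
            win = seq[start : start + 23]
            if any(c not in "ACGT" for c in win):
                continue
            # forward strand
            if pam_ok(win[20:]):
                mm = tuple(
                    i + 1 for i in range(20) if win[i] != protospacer[i]
                )
                if len(mm) <= max_mm:
                    hits.add((chrom, start, "+", win, mm))
            # reverse strand: the window read 5'->3' on the minus strand
            rcw = naive_revcomp(win)
            if pam_ok(rcw[20:]):
                mm = tuple(
                    i + 1 for i in range(20) if rcw[i] != protospacer[i]
                )
                if len(mm) <= max_mm:
                    hits.add((chrom, start, "-", rcw, mm))
    return hits


def pair_counting_roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC-AUC over all (positive, negative) pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
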