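"""Independent reference implementations used to cross-check the package.

These deliberately re-derive their tables and use different algorithms
(full O(n*m) dynamic programmes, literal codon lookups) so agreement with
the package is informative.
"""

from __future__ import annotations

import math

# literal IUPAC map, written out independently of phisigns.iupac
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def pairable(x: str, y: str) -> bool:
    return any(WC[a] in IUPAC[y] for a in IUPAC[x])


def brute_max_run(a: str, b: str) -> int:
    """Longest antiparallel complementary run by full DP over (i, j):
    run ending at a[i] paired with b-read-3'->5'[j]."""
    br = b[::-1]
    n, m = len(a), len(br)
    best = 0
    prev = [0] * m
    for i in range(n):
        cur = [0] * m
        for j in range(m):
            if pairable(a[i], br[j]):
                cur[j] = (prev[j - 1] if i > 0 and j > 0 else 0) + 1
                best = max(best, cur[j])
        prev = cur
    return best


def brute_hairpin_run(seq: str, min_loop: int = 3) -> int:
    """Longest hairpin stem by enumerating every (5' index, 3' index, depth)."""
    n = len(seq)
    best = 0
    for p in range(n):
        for q in range(n - 1, p, -1):
            k = 0
            while p + k < q - k and (q - k) - (p + k) - 1 >= min_loop \
                    and pairable(seq[p + k], seq[q - k]):
                k += 1
            best = max(best, k)
    return best


def nn_tm_oracle(seq: str, nn_rows: dict[str, tuple[float, float, float]],
                 na_conc: float = 0.05, primer_conc: float = 2.5e-7) -> float:
    """Nearest-neighbor Tm from the shared parameter rows, coded independently:
    explicit per-stack accumulation with initiation by terminal base class."""
    dh = 0.0
    ds = 0.0
    for stack in (seq[i] + seq[i + 1] for i in range(len(seq) - 1)):
        row = nn_rows[stack]
        dh += row[0]
        ds += row[1]
    for terminal in (seq[0], seq[-1]):
        row = nn_rows["init_GC"] if terminal in ("G", "C") else nn_rows["init_AT"]
        dh += row[0]
        ds += row[1]
    tm_kelvin = (dh * 1000.0) / (ds + 1.987 * math.log(primer_conc / 4.0))
    return tm_kelvin - 273.15 + 16.6 * math.log10(na_conc)


# codon table written out for the translation oracle (bacterial code: standard
# codons; only difference from the standard code is in start-codon policy,
# which does not affect internal translation)
CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(nt: str) -> str:
    aa = "".join(CODONS[nt[i:i + 3]] for i in range(0, len(nt), 3))
    return aa[:-1] if aa.endswith("*") else aa
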