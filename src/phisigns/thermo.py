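"""Primer enumeration and physicochemical property calculations.

Candidates are enumerated from conserved regions by a sliding window and
screened on degeneracy, GC content, GC clamp, melting temperature (three
methods), 3'-end stability and self-complementarity. Degenerate primers
are handled conservatively: GC-extreme disambiguations bound the melting
temperature, GC content is an expectation over the pool, free energies
take the most stable disambiguation, and complementarity uses
"can-pair" semantics (any disambiguation pair that is Watson-Crick).

Nearest-neighbor thermodynamics use the unified 1998 duplex parameter
set shipped as a TSV data file (ΔH kcal/mol, ΔS cal/mol/K, ΔG37
kcal/mol per dinucleotide stack plus terminal initiation terms).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from phisigns.consensus import ConservedRegion
from phisigns.genome_io import reverse_complement
from phisigns.iupac import CODE_SIZE, GAP, GC_FRACTION, VALID_CODES, disambiguation_set

R_GAS = 1.987  # cal / (mol K)


@dataclass
class ThermoParams:
    """Solution conditions for the thermodynamic calculations.

    na_conc: monovalent cation concentration (mol/L); primer_conc: total
    single-strand concentration (mol/L); nn_table: parameter-set name.
    """
    na_conc: float = 0.05
    primer_conc: float = 2.5e-7
    nn_table: str = "unified_1998"

    def __post_init__(self):
        if self.na_conc <= 0 or self.primer_conc <= 0:
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class PrimerCandidate:
    seq: str            # IUPAC, 5'->3' (reverse candidates are the revcomp of the window)
    region_id: str
    start: int          # 1-based inclusive consensus coordinates of the window
    stop: int
    orientation: str    # {forward, reverse}


@dataclass
class PrimerProperties:
    length: int
    degeneracy: int
    gc_percent: float
    gc_clamp: int
    tm_basic: tuple[float, float, float]   # (min, max, mid) over disambiguation extremes
    tm_salt: tuple[float, float, float]
    tm_nn: tuple[float, float, float]
    dg_3prime: float
    dg_min: float
    self_dimer_run: int
    hairpin_run: int


@lru_cache(maxsize=4)
def load_nn_table(name: str = "unified_1998") -> dict[str, tuple[float, float, float]]:
    """NN parameters {stack or init key: (dH, dS, dG37)} from the package data file."""
    table: dict[str, tuple[float, float, float]] = {}
    path = resources.files("phisigns.data") / f"nn_{name}.tsv"
    with path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[row["pair"]] = (float(row["dH_kcal_mol"]), float(row["dS_cal_mol_K"]),
                                  float(row["dG37_kcal_mol"]))
    return table


# --- enumeration -------------------------------------------------------------

def enumerate_primers(region: ConservedRegion, len_min: int = 10, len_max: int = 28,
                      orientation: str = "forward") -> list[PrimerCandidate]:
    """All windows of each length in [len_min, len_max] that fit in the region,
    one base at a time; reverse candidates carry the reverse complement of
    the consensus window. Duplicates by (seq, start, orientation) removed."""
    if len_min > len_max:
        raise ValueError("len_min must be <= len_max")
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"bad orientation {orientation!r}")
    out: list[PrimerCandidate] = []
    seen: set[tuple[str, int, str]] = set()
    for L in range(len_min, len_max + 1):
        for off in range(region.length - L + 1):
            window = region.seq[off:off + L]
            seq = window if orientation == "forward" else reverse_complement(window)
            start = region.start + off
            key = (seq, start, orientation)
            if key in seen:
                continue
            seen.add(key)
            out.append(PrimerCandidate(seq=seq, region_id=region.region_id, start=start,
                                       stop=start + L - 1, orientation=orientation))
    return out


# --- simple properties -------------------------------------------------------

def _check_iupac(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - VALID_CODES
    if bad:
        if GAP in bad:
            raise ValueError("gap character in primer sequence")
        raise ValueError(f"not an IUPAC nucleotide code: {sorted(bad)[0]!r}")
    return seq


def degeneracy(seq: str) -> int:
    """Number of exact sequences the degenerate primer encodes: the product
    of per-position IUPAC code sizes."""
    seq = _check_iupac(seq)
    d = 1
    for n in map(CODE_SIZE.__getitem__, seq):
        d *= n
    return d


def gc_content(seq: str) -> float:
    """Expected GC percentage over the primer pool (S counts 1, R counts 0.5, ...)."""
    seq = _check_iupac(seq)
    return 100.0 * sum(map(GC_FRACTION.__getitem__, seq)) / len(seq)


_CLAMP_CODES = frozenset("GCS")


def gc_clamp(seq: str) -> int:
    """Count of guaranteed G/C bases (codes G, C, S) among the five 3'-terminal
    bases; shorter sequences are counted over what is available."""
    seq = _check_iupac(seq)
    return sum(1 for ch in seq[-5:] if ch in _CLAMP_CODES)


# --- melting temperatures ----------------------------------------------------

_WEAK_ORDER = "ATCG"    # prefer A/T when resolving a degenerate position downward
_STRONG_ORDER = "GCAT"  # prefer G/C when resolving upward


def _resolve_table(order: str) -> dict[int, str]:
    return str.maketrans({c: next(b for b in order if b in disambiguation_set(c))
                          for c in "ACGTRYSWKMBDHVN"})


_WEAK_TRANS = _resolve_table(_WEAK_ORDER)
_STRONG_TRANS = _resolve_table(_STRONG_ORDER)


def _extremes(seq: str, fn) -> tuple[float, float, float]:
    lo = fn(seq.translate(_WEAK_TRANS))
    hi = fn(seq.translate(_STRONG_TRANS))
    lo, hi = min(lo, hi), max(lo, hi)
    return (lo, hi, (lo + hi) / 2.0)


def _tm_basic_exact(seq: str) -> float:
    n = len(seq)
    gc = seq.count("G") + seq.count("C")
    at = n - gc
    if n < 14:
        return 2.0 * at + 4.0 * gc   # Wallace rule
    return 64.9 + 41.0 * (gc - 16.4) / n


def tm_basic(seq: str) -> tuple[float, float, float]:
    """Basic melting temperature, °C, as (min, max, mid) over GC-extreme
    disambiguations: Wallace rule below 14 nt, Marmur-style formula above."""
    return _extremes(_check_iupac(seq), _tm_basic_exact)


def tm_salt(seq: str, params: ThermoParams | None = None) -> tuple[float, float, float]:
    """Salt-adjusted melting temperature, °C (min, max, mid)."""
    params = params or ThermoParams()
    salt = 16.6 * math.log10(params.na_conc)

    def f(s: str) -> float:
        n = len(s)
        if n < 14:
            return _tm_basic_exact(s) - 16.6 * math.log10(0.05) + salt
        gc_pct = 100.0 * (s.count("G") + s.count("C")) / n
        return 81.5 + salt + 0.41 * gc_pct - 675.0 / n

    return _extremes(_check_iupac(seq), f)


def _tm_nn_exact(seq: str, params: ThermoParams) -> float:
    table = load_nn_table(params.nn_table)
    dH = dS = 0.0
    for end in (seq[0], seq[-1]):
        h, s, _ = table["init_GC" if end in "GC" else "init_AT"]
        dH += h
        dS += s
    for i in range(len(seq) - 1):
        h, s, _ = table[seq[i:i + 2]]
        dH += h
        dS += s
    tm_k = 1000.0 * dH / (dS + R_GAS * math.log(params.primer_conc / 4.0))
    return tm_k - 273.15 + 16.6 * math.log10(params.na_conc)


def tm_nn(seq: str, params: ThermoParams | None = None) -> tuple[float, float, float]:
    """Nearest-neighbor melting temperature, °C (min, max, mid):
    Tm(K) = 1000·ΔH / (ΔS + R·ln(C/4)), salt-corrected by 16.6·log10[Na+]."""
    seq = _check_iupac(seq)
    if len(seq) < 2:
        raise ValueError("nearest-neighbor Tm needs length >= 2")
    params = params or ThermoParams()
    return _extremes(seq, lambda s: _tm_nn_exact(s, params))


# --- free energies -----------------------------------------------------------

def _dg37_most_stable(seq: str, params: ThermoParams) -> float:
    """Most negative stack ΔG37 over all disambiguations of *seq* (no initiation).

    Dynamic programme over positions: the state is the base chosen at the
    previous position, so degenerate sequences cost O(L·16) instead of
    enumerating the full pool.
    """
    table = load_nn_table(params.nn_table)
    sets = [sorted(disambiguation_set(ch)) for ch in seq]
    if len(sets) < 2:
        return 0.0
    best = {b: 0.0 for b in sets[0]}
    for cur in sets[1:]:
        best = {b2: min(best[b1] + table[b1 + b2][2] for b1 in best) for b2 in cur}
    return min(best.values())


def dg_3prime(seq: str, params: ThermoParams | None = None) -> float:
    """3'-end stability: NN ΔG37 (kcal/mol) summed over the stacks spanned by
    the five 3'-terminal bases, most stable disambiguation. Values at or
    above -9 kcal/mol are considered acceptable for pairing."""
    seq = _check_iupac(seq)
    params = params or ThermoParams()
    tail = seq[-5:]
    if len(tail) < 2:
        return 0.0
    return _dg37_most_stable(tail, params)


# --- complementarity ---------------------------------------------------------

# bitmask over {A,C,G,T} per IUPAC code, and the mask of bases a code can pair
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK = {code: sum(_BIT[b] for b in s) for code, s in
         ((c, disambiguation_set(c)) for c in "ACGTRYSWKMBDHVN")}
_COMP_BIT = {"A": _BIT["T"], "C": _BIT["G"], "G": _BIT["C"], "T": _BIT["A"]}
_PAIR_MASK = {code: sum(_COMP_BIT[b] for b in disambiguation_set(code)) for code in _MASK}


def _masks(seq: str) -> list[int]:
    return [_MASK[ch] for ch in seq]


def _pair_masks(seq: str) -> list[int]:
    return [_PAIR_MASK[ch] for ch in seq]


def _dimer_scan(a: str, b: str) -> tuple[int, int]:
    """(longest run, start of that run in *a*) of consecutive can-pair positions
    of *a* (5'->3') against *b* (3'->5'), over all ungapped offsets."""
    pm = _pair_masks(a)
    bm = _masks(b)[::-1]  # b read 3'->5'
    na, nb = len(pm), len(bm)
    best, best_start = 0, 0
    for off in range(-(nb - 1), na):
        run = 0
        start = 0
        for i in range(max(0, off), min(na, off + nb)):
            if pm[i] & bm[i - off]:
                if run == 0:
                    start = i
                run += 1
                if run > best:
                    best, best_start = run, start
            else:
                run = 0
    return best, best_start


def max_complementary_run(a: str, b: str) -> int:
    """Longest run of consecutive positions where *a* (5'->3') can pair *b*
    (3'->5'), maximised over all ungapped offsets. Self-dimer: run(a, a);
    cross-dimer: run(forward, reverse)."""
    return _dimer_scan(_check_iupac(a), _check_iupac(b))[0]


def _hairpin_scan(seq: str, min_loop: int = 3) -> tuple[int, int]:
    """(longest stem run, stem start) between a 5' arm and the reversed 3' arm
    with a loop of at least *min_loop* bases."""
    pm = _pair_masks(seq)
    m = _masks(seq)
    n = len(seq)
    best, best_start = 0, 0
    for p in range(n):
        for q in range(p + min_loop + 1, n):
            run = 0
            t = 0
            while (q - t) - (p + t) - 1 >= min_loop and pm[p + t] & m[q - t]:
                run += 1
                t += 1
            if run > best:
                best, best_start = run, p
    return best, best_start


def hairpin_run(seq: str, min_loop: int = 3) -> int:
    """Longest intramolecular stem (consecutive can-pair positions between a
    5' arm and the reversed 3' arm) with a loop of at least *min_loop* bases."""
    return _hairpin_scan(_check_iupac(seq), min_loop)[0]


def dg_min(seq: str, params: ThermoParams | None = None) -> float:
    """ΔG37 (kcal/mol) of the most stable self-structure stretch found by the
    run searches (self-dimer and hairpin stem); 0 when no run of >= 2 exists.
    Reported for information; not filtered on by default."""
    seq = _check_iupac(seq)
    params = params or ThermoParams()
    vals = [0.0]
    for run, start in (_dimer_scan(seq, seq), _hairpin_scan(seq)):
        if run >= 2:
            vals.append(_dg37_most_stable(seq[start:start + run], params))
    return min(vals)


# --- bundle ------------------------------------------------------------------

def compute_properties(seq: str, params: ThermoParams | None = None) -> PrimerProperties:
    """Full property block for one primer sequence."""
    seq = _check_iupac(seq)
    params = params or ThermoParams()
    sd_run, sd_start = _dimer_scan(seq, seq)
    hp_run, hp_start = _hairpin_scan(seq)
    dg_vals = [0.0]
    for run, start in ((sd_run, sd_start), (hp_run, hp_start)):
        if run >= 2:
            dg_vals.append(_dg37_most_stable(seq[start:start + run], params))
    return PrimerProperties(
        length=len(seq),
        degeneracy=degeneracy(seq),
        gc_percent=gc_content(seq),
        gc_clamp=gc_clamp(seq),
        tm_basic=tm_basic(seq),
        tm_salt=tm_salt(seq, params),
        tm_nn=tm_nn(seq, params),
        dg_3prime=dg_3prime(seq, params),
        dg_min=min(dg_vals),
        self_dimer_run=sd_run,
        hairpin_run=hp_run,
    )
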