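"""Primer screening, Tm-matched pairing, and in-silico recovery checks.

Forward candidates are consensus windows read 5'->3'; reverse candidates
are reverse complements of downstream windows. Pairs are ranked by the
difference in nearest-neighbor melting temperature (mid value), so the
best pair is the most thermally matched one that satisfies every
user-constraint.
"""

from __future__ import annotations

import configparser
import csv
import logging
import math
from dataclasses import dataclass, field

from phisigns.consensus import CodonAlignment, ConservedRegion, ConsensusSequence, extract_conserved_regions, iupac_consensus
from phisigns.genome_io import GeneRecord, reverse_complement
from phisigns.iupac import GAP, matches
from phisigns.thermo import (
    PrimerCandidate,
    PrimerProperties,
    ThermoParams,
    compute_properties,
    enumerate_primers,
    max_complementary_run,
)

log = logging.getLogger("phisigns")

_INF = math.inf


@dataclass
class DesignParams:
    """User-tunable primer and product constraints (min/max pairs).

    Defaults follow common degenerate-primer practice: 10-28 nt primers,
    GC clamp at most 3 of the last five bases, 3' stability floor of
    -9 kcal/mol, and dimer/hairpin runs strictly below 5 consecutive
    pairings.
    """
    len_min: int = 10
    len_max: int = 28
    product_min: int = 100
    product_max: int = 3000
    degeneracy_max: int = 512
    gc_min: float = 0.0
    gc_max: float = 100.0
    clamp_min: int = 0
    clamp_max: int = 3
    tm_min: float = -_INF
    tm_max: float = _INF
    dg3_floor: float = -9.0
    max_run: int = 4            # dimer/hairpin runs must be <= this (i.e. < 5)
    delta_tm_max: float = _INF
    tm_method: str = "nn"       # pairing/screening Tm: {basic, salt, nn}, mid value
    top_k: int = 100
    thermo: ThermoParams = field(default_factory=ThermoParams)

    def __post_init__(self):
        for lo, hi, name in [(self.len_min, self.len_max, "length"),
                             (self.product_min, self.product_max, "product size"),
                             (self.gc_min, self.gc_max, "GC%"),
                             (self.clamp_min, self.clamp_max, "GC clamp"),
                             (self.tm_min, self.tm_max, "Tm")]:
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")

    @classmethod
    def from_file(cls, path) -> "DesignParams":
        """Read key=value parameter file (INI-style, section optional)."""
        cp = configparser.ConfigParser()
        with open(path) as fh:
            text = fh.read()
        if not text.lstrip().startswith("["):
            text = "[primers]\n" + text
        cp.read_string(text)
        kv = {k: v for sec in cp.sections() for k, v in cp.items(sec)}
        kwargs = {}
        thermo_kwargs = {}
        for k, v in kv.items():
            if k in ("na_conc", "primer_conc"):
                thermo_kwargs[k] = float(v)
            elif k == "nn_table":
                thermo_kwargs[k] = v
            elif k in ("tm_method",):
                kwargs[k] = v
            elif k in ("len_min", "len_max", "product_min", "product_max",
                       "degeneracy_max", "clamp_min", "clamp_max", "max_run", "top_k"):
                kwargs[k] = int(v)
            elif k in ("gc_min", "gc_max", "tm_min", "tm_max", "dg3_floor", "delta_tm_max"):
                kwargs[k] = float(v)
            else:
                raise ValueError(f"unknown parameter {k!r} in {path}")
        if thermo_kwargs:
            kwargs["thermo"] = ThermoParams(**thermo_kwargs)
        return cls(**kwargs)

    def tm_mid(self, props: PrimerProperties) -> float:
        return {"basic": props.tm_basic, "salt": props.tm_salt, "nn": props.tm_nn}[self.tm_method][2]


@dataclass
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    forward_props: PrimerProperties
    reverse_props: PrimerProperties
    product_size: int
    delta_tm: float
    cross_dimer_run: int


# --- screening ---------------------------------------------------------------

def passes_screens(props: PrimerProperties, params: DesignParams) -> bool:
    """Pure predicate: does a property block satisfy every range/threshold?"""
    return (params.len_min <= props.length <= params.len_max
            and props.degeneracy <= params.degeneracy_max
            and params.gc_min <= props.gc_percent <= params.gc_max
            and params.clamp_min <= props.gc_clamp <= params.clamp_max
            and params.tm_min <= params.tm_mid(props) <= params.tm_max
            and props.dg_3prime >= params.dg3_floor
            and props.self_dimer_run <= params.max_run
            and props.hairpin_run <= params.max_run)


_SCREENS = [
    ("length", lambda p, d: d.len_min <= p.length <= d.len_max),
    ("degeneracy", lambda p, d: p.degeneracy <= d.degeneracy_max),
    ("gc_percent", lambda p, d: d.gc_min <= p.gc_percent <= d.gc_max),
    ("gc_clamp", lambda p, d: d.clamp_min <= p.gc_clamp <= d.clamp_max),
    ("tm", lambda p, d: d.tm_min <= d.tm_mid(p) <= d.tm_max),
    ("dg_3prime", lambda p, d: p.dg_3prime >= d.dg3_floor),
    ("self_dimer", lambda p, d: p.self_dimer_run <= d.max_run),
    ("hairpin", lambda p, d: p.hairpin_run <= d.max_run),
]


def screen_candidates(candidates: list[PrimerCandidate], props: dict[str, PrimerProperties],
                      params: DesignParams) -> list[PrimerCandidate]:
    """Retain candidates passing every screen; per-screen attrition is logged."""
    attrition = {name: 0 for name, _ in _SCREENS}
    survivors = []
    for c in candidates:
        p = props[c.seq]
        failed = False
        for name, pred in _SCREENS:
            if not pred(p, params):
                attrition[name] += 1
                failed = True
                break
        if not failed:
            survivors.append(c)
    log.info("screened %d candidates -> %d survivors (attrition: %s)",
             len(candidates), len(survivors),
             ", ".join(f"{k}={v}" for k, v in attrition.items() if v))
    return survivors


def _cheap_tm_mid(seq: str, params: DesignParams) -> float:
    from phisigns import thermo as T
    if params.tm_method == "basic":
        return T.tm_basic(seq)[2]
    if params.tm_method == "salt":
        return T.tm_salt(seq, params.thermo)[2]
    return T.tm_nn(seq, params.thermo)[2]


def _cheap_pass(seq: str, params: DesignParams) -> bool:
    """Range screens that need no complementarity scan or NN ΔG work."""
    from phisigns import thermo as T
    if not (params.len_min <= len(seq) <= params.len_max):
        return False
    if T.degeneracy(seq) > params.degeneracy_max:
        return False
    if not (params.gc_min <= T.gc_content(seq) <= params.gc_max):
        return False
    if not (params.clamp_min <= T.gc_clamp(seq) <= params.clamp_max):
        return False
    if math.isfinite(params.tm_min) or math.isfinite(params.tm_max):
        if not (params.tm_min <= _cheap_tm_mid(seq, params) <= params.tm_max):
            return False
    return True


# --- pairing -----------------------------------------------------------------

def _pair_ranked(forwards: list[PrimerCandidate], reverses: list[PrimerCandidate],
                 params: DesignParams, props: dict[str, PrimerProperties],
                 limit: int | None = None, lazy: bool = False) -> tuple[list[PrimerPair], int]:
    """Rank acceptable pairs by (|ΔTm|, degeneracy product, coordinates).

    Position/product/ΔTm eligibility is evaluated vectorised. The pair
    ranking depends only on cheap per-candidate quantities, so with
    lazy=True the costly per-candidate screens (self-dimer, hairpin,
    3' ΔG) and the cross-dimer test are evaluated walking down the
    ranked order, stopping once *limit* pairs are accepted — the output
    is identical to exhaustive screening. Returns (pairs, n_eligible)
    where n_eligible counts ranked combinations before those tests.
    """
    import numpy as np
    from phisigns.thermo import degeneracy as _deg

    if lazy:
        fs, rs = list(forwards), list(reverses)
    else:
        # both 3' ends must meet the ΔG floor before pairing
        fs = [f for f in forwards if props[f.seq].dg_3prime >= params.dg3_floor]
        rs = [r for r in reverses if props[r.seq].dg_3prime >= params.dg3_floor]
    if not fs or not rs:
        return [], 0

    tm_cache: dict[str, float] = {}

    def tmmid(seq: str) -> float:
        if seq in props:
            return params.tm_mid(props[seq])
        v = tm_cache.get(seq)
        if v is None:
            v = tm_cache[seq] = _cheap_tm_mid(seq, params)
        return v

    f_start = np.array([f.start for f in fs])
    f_stop = np.array([f.stop for f in fs])
    r_start = np.array([r.start for r in rs])
    r_stop = np.array([r.stop for r in rs])
    tm_f = np.array([tmmid(f.seq) for f in fs])
    tm_r = np.array([tmmid(r.seq) for r in rs])
    deg_f = np.array([_deg(f.seq) for f in fs], dtype=float)
    deg_r = np.array([_deg(r.seq) for r in rs], dtype=float)

    screen_ok: dict[str, bool] = {}

    def full_props_ok(seq: str) -> bool:
        ok = screen_ok.get(seq)
        if ok is None:
            if seq not in props:
                props[seq] = compute_properties(seq, params.thermo)
            ok = screen_ok[seq] = passes_screens(props[seq], params)
        return ok

    def _block(sl: slice):
        """Position/product/ΔTm eligibility for a block of forwards vs all reverses."""
        size = r_stop[None, :] - f_start[sl, None] + 1
        mask = (f_stop[sl, None] < r_start[None, :]) \
            & (size >= params.product_min) & (size <= params.product_max)
        dt = np.abs(tm_f[sl, None] - tm_r[None, :])
        if math.isfinite(params.delta_tm_max):
            mask &= dt <= params.delta_tm_max
        return mask, dt

    def walk(fi: np.ndarray, ri: np.ndarray, d: np.ndarray) -> list[PrimerPair]:
        order = np.lexsort((r_stop[ri], f_stop[fi], r_start[ri], f_start[fi],
                            deg_f[fi] * deg_r[ri], d))
        cross_memo: dict[tuple[str, str], int] = {}
        pairs: list[PrimerPair] = []
        for k in order:
            f, r = fs[fi[k]], rs[ri[k]]
            if lazy and not (full_props_ok(f.seq) and full_props_ok(r.seq)):
                continue
            if props[f.seq].dg_3prime < params.dg3_floor or props[r.seq].dg_3prime < params.dg3_floor:
                continue
            key = (f.seq, r.seq)
            cross = cross_memo.get(key)
            if cross is None:
                cross = cross_memo[key] = max_complementary_run(f.seq, r.seq)
            if cross > params.max_run:
                continue
            pairs.append(PrimerPair(forward=f, reverse=r, forward_props=props[f.seq],
                                    reverse_props=props[r.seq],
                                    product_size=int(r.stop - f.start + 1),
                                    delta_tm=float(d[k]), cross_dimer_run=cross))
            if limit is not None and len(pairs) >= limit:
                break
        return pairs

    F, R = len(fs), len(rs)
    block = max(1, 2_000_000 // max(R, 1))

    if limit is None or F * R <= 4_000_000:
        fis, ris, ds = [], [], []
        n_eligible = 0
        for f0 in range(0, F, block):
            sl = slice(f0, min(F, f0 + block))
            mask, dt = _block(sl)
            bi, bj = np.nonzero(mask)
            n_eligible += len(bi)
            fis.append(bi + f0)
            ris.append(bj)
            ds.append(dt[bi, bj])
        if n_eligible == 0:
            return [], 0
        return walk(np.concatenate(fis), np.concatenate(ris), np.concatenate(ds)), n_eligible

    # large problem with a top-K request: chunked selection of every
    # combination whose ΔTm can reach the top ranks (ties at the boundary
    # kept, so the ranking below is exact), enlarging the selection if
    # the screens reject too much
    K = 50 * limit
    n_eligible = None
    while True:
        cut = np.inf
        sel_f, sel_r, sel_d = [], [], []
        acc = 0
        total = 0
        for f0 in range(0, F, block):
            sl = slice(f0, min(F, f0 + block))
            mask, dt = _block(sl)
            total += int(mask.sum())
            mask &= dt <= cut
            bi, bj = np.nonzero(mask)
            sel_f.append(bi + f0)
            sel_r.append(bj)
            sel_d.append(dt[bi, bj])
            acc += len(bi)
            if acc > 8 * K:
                d_all = np.concatenate(sel_d)
                if len(d_all) > K:
                    cut = np.partition(d_all, K)[K]
                    keep = d_all <= cut
                    sel_f = [np.concatenate(sel_f)[keep]]
                    sel_r = [np.concatenate(sel_r)[keep]]
                    sel_d = [d_all[keep]]
                    acc = len(sel_d[0])
        n_eligible = total
        if n_eligible == 0:
            return [], 0
        fi = np.concatenate(sel_f)
        ri = np.concatenate(sel_r)
        d = np.concatenate(sel_d)
        if len(d) > K:
            cut = np.partition(d, K)[K]
            keep = d <= cut
            fi, ri, d = fi[keep], ri[keep], d[keep]
        pairs = walk(fi, ri, d)
        if len(pairs) >= limit or len(d) >= n_eligible:
            return pairs, n_eligible
        K *= 8  # selection too small after screening; widen and retry


def pair_primers(forwards: list[PrimerCandidate], reverses: list[PrimerCandidate],
                 params: DesignParams,
                 props: dict[str, PrimerProperties] | None = None) -> list[PrimerPair]:
    """All acceptable (forward, reverse) combinations, ranked by |ΔTm|.

    A pair is acceptable when the forward window lies strictly upstream
    of the reverse window, the consensus product size is in range, the
    cross-dimer run stays within the configured maximum, and both 3'
    ends meet the ΔG floor. Ties in ΔTm break by the smaller product of
    degeneracies, then by coordinates.
    """
    props = props if props is not None else {}
    for c in list(forwards) + list(reverses):
        if c.seq not in props:
            props[c.seq] = compute_properties(c.seq, params.thermo)
    pairs, _ = _pair_ranked(forwards, reverses, params, props, limit=None)
    return pairs


# --- in-silico recovery ------------------------------------------------------

@dataclass
class MemberMatch:
    member_id: str
    forward_mismatches: int
    reverse_mismatches: int
    amplicon_length: int
    flagged: bool = False   # primer site spans an alignment gap for this member


def _site_mismatches(primer_consensus_strand: str, member_site: str) -> int:
    return sum(0 if matches(code, base) else 1
               for code, base in zip(primer_consensus_strand, member_site))


def in_silico_recovery(pair: PrimerPair, alignment: CodonAlignment) -> list[MemberMatch]:
    """IUPAC-aware match of the pair against every member of the alignment.

    The forward primer is compared at its consensus columns on the coding
    strand; the reverse primer is compared as its reverse complement
    (i.e. the consensus-strand window it was derived from). Reported
    amplicon lengths are member-specific ungapped lengths between the
    outer primer bounds.
    """
    f, r = pair.forward, pair.reverse
    rev_on_consensus = reverse_complement(r.seq)
    out: list[MemberMatch] = []
    for mid, row in zip(alignment.member_ids, alignment.rows):
        f_site = row[f.start - 1: f.stop]
        r_site = row[r.start - 1: r.stop]
        if GAP in f_site or GAP in r_site:
            out.append(MemberMatch(member_id=mid, forward_mismatches=-1,
                                   reverse_mismatches=-1, amplicon_length=0, flagged=True))
            continue
        amplicon = row[f.start - 1: r.stop].replace(GAP, "")
        out.append(MemberMatch(
            member_id=mid,
            forward_mismatches=_site_mismatches(f.seq, f_site),
            reverse_mismatches=_site_mismatches(rev_on_consensus, r_site),
            amplicon_length=len(amplicon)))
    return out


# --- end-to-end design -------------------------------------------------------

@dataclass
class DesignResult:
    alignment: CodonAlignment
    consensus: ConsensusSequence
    regions: list[ConservedRegion]
    pairs: list[PrimerPair]            # ranked, truncated to top_k
    n_pairs_total: int                 # combinations eligible before the cross-dimer test
    n_candidates: int                  # enumerated windows before screening
    recovery: dict[int, list[MemberMatch]] = field(default_factory=dict)  # rank -> matches


def design_primers(genes: list[GeneRecord] | None, params: DesignParams | None = None,
                   alignment: CodonAlignment | None = None,
                   aligner: str = "mafft") -> DesignResult:
    """Run the full design stage for one signature-gene group.

    Either *genes* (auto alignment via the external aligner) or a
    prebuilt *alignment* must be given.
    """
    from phisigns.consensus import align_group

    params = params or DesignParams()
    if alignment is None:
        if genes is None or len(genes) < 2:
            raise ValueError("design needs >=2 genes or an alignment")
        alignment = align_group(genes, aligner=aligner)
    cons = iupac_consensus(alignment)
    regions = extract_conserved_regions(cons, min_keep=params.len_min)
    if not regions:
        log.info("no conserved regions in consensus of length %d; empty report", len(cons))
        return DesignResult(alignment=alignment, consensus=cons, regions=[], pairs=[],
                            n_pairs_total=0, n_candidates=0)
    # enumerate once per orientation, deduplicating windows shared by
    # overlapping regions; cheap screens run before the costly
    # complementarity/ΔG properties are computed
    raw: dict[str, list[PrimerCandidate]] = {"forward": [], "reverse": []}
    seen: set[tuple[str, int, str]] = set()
    for region in regions:
        for orientation in ("forward", "reverse"):
            for c in enumerate_primers(region, params.len_min, params.len_max, orientation):
                key = (c.seq, c.start, c.orientation)
                if key not in seen:
                    seen.add(key)
                    raw[orientation].append(c)
    n_candidates = len(raw["forward"]) + len(raw["reverse"])
    cheap_ok: dict[str, bool] = {}
    props: dict[str, PrimerProperties] = {}
    forwards: list[PrimerCandidate] = []
    reverses: list[PrimerCandidate] = []
    for orientation, sink in (("forward", forwards), ("reverse", reverses)):
        for c in raw[orientation]:
            ok = cheap_ok.get(c.seq)
            if ok is None:
                ok = cheap_ok[c.seq] = _cheap_pass(c.seq, params)
            if ok:
                sink.append(c)
    log.info("%d enumerated candidates, %d past the range screens "
             "(%d forward, %d reverse)", n_candidates,
             len(forwards) + len(reverses), len(forwards), len(reverses))
    pairs, n_total = _pair_ranked(forwards, reverses, params, props,
                                  limit=params.top_k, lazy=True)
    recovery = {rank: in_silico_recovery(p, alignment) for rank, p in enumerate(pairs, 1)}
    return DesignResult(alignment=alignment, consensus=cons, regions=regions, pairs=pairs,
                        n_pairs_total=n_total, n_candidates=n_candidates, recovery=recovery)


def write_primer_report(result: DesignResult, path) -> None:
    """Ranked primer-pair report TSV."""
    def fmt_tm(t):
        return "/".join(f"{x:.1f}" for x in t)

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["rank", "fwd_seq", "fwd_start", "fwd_stop", "fwd_len", "fwd_degeneracy",
                    "fwd_gc", "fwd_clamp", "fwd_tm_basic", "fwd_tm_salt", "fwd_tm_nn",
                    "fwd_dg3", "fwd_self_dimer", "fwd_hairpin",
                    "rev_seq", "rev_start", "rev_stop", "rev_len", "rev_degeneracy",
                    "rev_gc", "rev_clamp", "rev_tm_basic", "rev_tm_salt", "rev_tm_nn",
                    "rev_dg3", "rev_self_dimer", "rev_hairpin",
                    "product_size", "delta_tm", "cross_dimer_run"])
        for rank, p in enumerate(result.pairs, 1):
            row = [rank]
            for cand, pr in ((p.forward, p.forward_props), (p.reverse, p.reverse_props)):
                row += [cand.seq, cand.start, cand.stop, pr.length, pr.degeneracy,
                        f"{pr.gc_percent:.1f}", pr.gc_clamp, fmt_tm(pr.tm_basic),
                        fmt_tm(pr.tm_salt), fmt_tm(pr.tm_nn), f"{pr.dg_3prime:.2f}",
                        pr.self_dimer_run, pr.hairpin_run]
            row += [p.product_size, f"{p.delta_tm:.2f}", p.cross_dimer_run]
            w.writerow(row)
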