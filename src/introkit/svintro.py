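"""Population-specific SV detection and introgression assignment.

Each SV is scored with the single-locus Weir-Cockerham F_ST between two
sample groups, an empirical P-value from label permutations, and the
four-way specificity filter (top-quantile F_ST, empirical P, missingness,
MAF).  Specific SVs flanked by inferred introgression segments are
classified as introgressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .fstats import wc_fst
from .genio import MISSING, SVRecord
from .introcall import IntrogressedSegment


@dataclass
class SVIntrogressionCall:
    sv: SVRecord
    fst: float
    empirical_p: float
    specific: bool = False
    flanking_segment: int | None = None  # index into the segment list
    classification: str = "none"  # {"recipient-like", "none"}


def _group_dosages(sv: SVRecord, sample_ids: list[str]) -> np.ndarray:
    idx = {s: i for i, s in enumerate(sv.sample_ids)}
    try:
        rows = [idx[s] for s in sample_ids]
    except KeyError as exc:
        raise ArgumentError(f"sample {exc.args[0]!r} absent from SV genotypes")
    return sv.genotypes[rows]


def _fst_from_dosages(d_a: np.ndarray, d_b: np.ndarray) -> float:
    stats = []
    for d in (d_a, d_b):
        called = d != MISSING
        n = int(called.sum())
        if n == 0:
            return float("nan")
        p = d[called].sum() / (2.0 * n)
        h = float(((d == 1) & called).sum()) / n
        stats.append((n, p, h))
    (na, pa, ha), (nb, pb, hb) = stats
    if (pa in (0.0, 1.0)) and pa == pb:
        return float("nan")  # monomorphic in both groups
    return wc_fst(
        np.array([na, nb], dtype=float),
        np.array([pa, pb], dtype=float),
        np.array([ha, hb], dtype=float),
    )


def sv_fst(sv: SVRecord, group_a: list[str], group_b: list[str]) -> float:
    """Single-locus WC84 F_ST for one SV between two sample groups."""
    return _fst_from_dosages(_group_dosages(sv, group_a), _group_dosages(sv, group_b))


def _fst_many(dosages: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """WC84 F_ST for many label assignments at once.

    ``dosages``: (n_samples,) int8 with MISSING; ``membership``: boolean
    (n_assignments, n_samples), True marks group A.  Returns one F_ST per
    assignment (NaN where undefined).
    """
    d = dosages.astype(float)
    called = dosages != MISSING
    het = (dosages == 1) & called
    dos0 = np.where(called, d, 0.0)

    def group_stats(mask: np.ndarray):
        n = (mask & called).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (mask * dos0).sum(axis=1) / (2 * np.maximum(n, 1))
            h = (mask & het).sum(axis=1) / np.maximum(n, 1)
        return n, p, h

    na, pa, ha = group_stats(membership)
    nb, pb, hb = group_stats(~membership)
    bad = (na == 0) | (nb == 0)
    n = np.stack([na, nb])
    p = np.stack([pa, pb])
    h = np.stack([ha, hb])
    r = 2
    n_bar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        den = a + b + c
        fst = np.where(den != 0, a / np.where(den != 0, den, 1.0), np.nan)
    fst[bad] = np.nan
    # monomorphic across both groups -> undefined
    mono = (p_bar == 0) | (p_bar == 1)
    fst[mono] = np.nan
    return fst


def permutation_empirical_p(
    sv: SVRecord,
    group_a: list[str],
    group_b: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation empirical P for one SV's group F_ST.

    Sample (diploid) labels are shuffled ``n_perm`` times and
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` (add-one estimator).
    Returns ``(fst_observed, empirical_p)``; P is NaN when the observed
    F_ST is undefined.
    """
    if n_perm < 100:
        raise ArgumentError("n_perm must be >= 100")
    rng = rng if rng is not None else np.random.default_rng(seed)
    samples = list(group_a) + list(group_b)
    dosages = _group_dosages(sv, samples)
    n_a = len(group_a)
    observed = _fst_from_dosages(dosages[:n_a], dosages[n_a:])
    if np.isnan(observed):
        return observed, float("nan")
    n = len(samples)
    membership = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        membership[i, rng.permutation(n)[:n_a]] = True
    perm_fst = _fst_many(dosages, membership)
    exceed = int(np.sum(perm_fst[~np.isnan(perm_fst)] >= observed - 1e-12))
    exceed += int(np.isnan(perm_fst).sum())  # undefined permutations tie conservatively
    return observed, (1 + exceed) / (1 + n_perm)


def filter_specific(
    calls: list[SVIntrogressionCall],
    fst_quantile: float = 0.95,
    p_max: float = 0.05,
    miss_max: float = 0.1,
    maf_min: float = 0.01,
    group_a: list[str] | None = None,
    group_b: list[str] | None = None,
) -> dict[str, int]:
    """Flag population-specific SVs in place.

    An SV is specific iff (1) its F_ST is strictly above the
    ``fst_quantile`` quantile of the tested set, (2) its empirical P is
    below ``p_max``, (3) its missingness is below ``miss_max`` and (4) its
    MAF is above ``maf_min``.  MAF and missingness are computed over the
    union of the two compared groups when given.  Returns the per-criterion
    failure counts.
    """
    fsts = np.array([c.fst for c in calls], dtype=float)
    tested = fsts[~np.isnan(fsts)]
    cut = float(np.quantile(tested, fst_quantile)) if tested.size else float("inf")
    fails = {"fst": 0, "p": 0, "missingness": 0, "maf": 0}
    for call in calls:
        if group_a is not None and group_b is not None:
            d = _group_dosages(call.sv, list(group_a) + list(group_b))
            called = d != MISSING
            miss = 1.0 - called.sum() / d.size
            if called.sum():
                af = d[called].sum() / (2.0 * called.sum())
                maf = min(af, 1.0 - af)
            else:
                maf = float("nan")
        else:
            miss, maf = call.sv.missingness, call.sv.maf
        ok = True
        if np.isnan(call.fst) or call.fst <= cut:
            fails["fst"] += 1
            ok = False
        if np.isnan(call.empirical_p) or call.empirical_p >= p_max:
            fails["p"] += 1
            ok = False
        if miss >= miss_max:
            fails["missingness"] += 1
            ok = False
        if np.isnan(maf) or maf <= maf_min:
            fails["maf"] += 1
            ok = False
        call.specific = ok
    return fails


def assign_flanking(
    calls: list[SVIntrogressionCall],
    segments: list[IntrogressedSegment],
    max_gap: int = 0,
) -> list[SVIntrogressionCall]:
    """Classify specific SVs whose footprint overlaps (or lies within
    ``max_gap`` bp of) an inferred introgression segment."""
    for call in calls:
        call.flanking_segment = None
        call.classification = "none"
        if not call.specific:
            continue
        lo, hi = call.sv.interval()
        for k, seg in enumerate(segments):
            if seg.chrom == call.sv.chrom and lo - max_gap < seg.end and seg.start < hi + max_gap:
                call.flanking_segment = k
                call.classification = "recipient-like"
                break
    return calls


def run_sv_scan(
    svs: list[SVRecord],
    group_a: list[str],
    group_b: list[str],
    segments: list[IntrogressedSegment] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    fst_quantile: float = 0.95,
    p_max: float = 0.05,
    miss_max: float = 0.1,
    maf_min: float = 0.01,
    max_gap: int = 0,
) -> list[SVIntrogressionCall]:
    """Full SV pipeline: F_ST, permutation P, specificity filter, flanking."""
    rng = np.random.default_rng(seed)
    calls = []
    for sv in svs:
        fst, p = permutation_empirical_p(sv, group_a, group_b, n_perm=n_perm, rng=rng)
        calls.append(SVIntrogressionCall(sv=sv, fst=fst, empirical_p=p))
    filter_specific(
        calls,
        fst_quantile=fst_quantile,
        p_max=p_max,
        miss_max=miss_max,
        maf_min=maf_min,
        group_a=group_a,
        group_b=group_b,
    )
    if segments is not None:
        assign_flanking(calls, segments, max_gap=max_gap)
    return calls


def call_table(calls: list[SVIntrogressionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.sv.sv_id,
                c.sv.svtype,
                c.sv.chrom,
                c.sv.pos,
                c.sv.end,
                c.fst,
                c.empirical_p,
                c.specific,
                c.flanking_segment if c.flanking_segment is not None else "NA",
                c.classification,
            )
            for c in calls
        ],
        columns=[
            "sv_id", "svtype", "chrom", "pos", "end",
            "fst", "empirical_p", "specific", "segment_id", "classification",
        ],
    )
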