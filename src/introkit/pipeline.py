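"""End-to-end driver: simulate -> rIBD scan -> D/f_d -> segment calling ->
SV scan -> summary.  Shared by the CLI, the test-suite and the acceptance
report so that every consumer runs the identical code path."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fstats, ibdscan, introcall, simdata, svintro
from .errors import InsufficientDataError
from .genio import GenomicWindow, HaplotypePanel, PopulationMap, make_windows
from .simdata import SimulationConfig, TruthTract


@dataclass
class ScanParams:
    """Knobs for the window scans and the segment caller."""

    window: int = 50_000
    step: int = 25_000
    q: float = 0.01
    fd_min: float = 0.0
    delta: float = 0.0
    gap: int = 250_000
    extend: bool = True
    min_sites_d: int = 10
    ibd_min_length: int = 250_000
    ibd_min_sites: int = 120
    ibd_max_mismatch: int = 6
    min_window_sites: int = 10
    jackknife_block: int = 1_000_000
    n_perm: int = 1000
    fst_quantile: float = 0.95
    p_max: float = 0.05
    miss_max: float = 0.1
    maf_min: float = 0.01
    sv_max_gap: int = 0
    min_run_windows: int = 6
    veto_margin: float = float("inf")
    #: windows need this much rIBD (fraction of cross pairs) to extend a run;
    #: deep-coalescence sharing clusters in null data stay below it
    member_floor: float = 0.0175


def null_config(seed: int, **overrides) -> SimulationConfig:
    """Desk-scale no-gene-flow configuration: 5 Mb, 40-haplotype panels.

    Populations carry a larger census than the exported panels; with a
    40-haplotype census the tip splits act as founder events whose sampling
    asymmetry is correlated across the whole genome, which inflates the
    genome-wide D in a way no block jackknife can capture.
    """
    kwargs = dict(
        chromosome_length=5_000_000,
        n_sites=6_000,
        pop_sizes={"P_A": 40, "P_B": 240, "W_A": 40, "W_B": 40, "OUT": 40},
        sample_sizes={"P_B": 40},
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def pulse_config(
    seed: int, proportion: float = 0.2, generation: int = 30, **overrides
) -> SimulationConfig:
    """One-way pulse configuration used for recovery benchmarking.

    The recipient population carries a larger census than the exported
    40-haplotype panel so that the pulse survives post-admixture drift and
    each region keeps several donor lineages.
    """
    kwargs = dict(
        chromosome_length=20_000_000,
        n_sites=24_000,
        pop_sizes={"P_A": 40, "P_B": 240, "W_A": 40, "W_B": 40, "OUT": 40},
        sample_sizes={"P_B": 40},
        pulse_specs=[simdata.PulseSpec(generation, "P_A", "P_B", proportion)],
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@dataclass
class DirectionResult:
    donor: str
    recipient: str
    background: str
    ribd_windows: list
    fd_same: np.ndarray
    fd_opp: np.ndarray
    segments: list
    genome_fraction: float


def _roles(popmap: PopulationMap, recipient: str, donor: str, background: str,
           outgroup: str) -> PopulationMap:
    return PopulationMap(
        assignments=dict(popmap.assignments),
        roles={
            "recipient": recipient,
            "donor": donor,
            "background": background,
            "outgroup": outgroup,
        },
    )


def scan_direction(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    donor: str,
    recipient: str,
    background_of: dict[str, str],
    outgroup: str,
    chrom_length: int,
    params: ScanParams,
    windows: list[GenomicWindow] | None = None,
) -> DirectionResult:
    """rIBD + both-arrangement f_d + segment calls for one flow direction."""
    if windows is None:
        windows = make_windows(chrom_length, params.window, params.step,
                               chrom=panel.chrom)
    roles = _roles(popmap, recipient, donor, background_of[recipient], outgroup)
    ribd = ibdscan.ribd_scan(
        panel,
        roles,
        windows,
        min_length=params.ibd_min_length,
        min_sites=params.ibd_min_sites,
        max_mismatch=params.ibd_max_mismatch,
        chrom_length=chrom_length,
        min_window_sites=params.min_window_sites,
    )
    fq_same = fstats.quartet_freqs(
        panel, popmap, background_of[recipient], recipient, donor, outgroup
    )
    fq_opp = fstats.quartet_freqs(
        panel, popmap, background_of[donor], donor, recipient, outgroup
    )
    fd_same = np.array(
        [fstats.window_dstats(fq_same, w, params.min_sites_d)[1] for w in windows]
    )
    fd_opp = np.array(
        [fstats.window_dstats(fq_opp, w, params.min_sites_d)[1] for w in windows]
    )
    segments = introcall.call_segments(
        ribd,
        fd_same,
        fd_opp,
        direction_label=f"{donor}->{recipient}",
        q=params.q,
        fd_min=params.fd_min,
        delta=params.delta,
        gap=params.gap,
        extend=params.extend,
        min_run_windows=params.min_run_windows,
        veto_margin=params.veto_margin,
        member_floor=params.member_floor,
    )
    return DirectionResult(
        donor=donor,
        recipient=recipient,
        background=background_of[recipient],
        ribd_windows=ribd,
        fd_same=fd_same,
        fd_opp=fd_opp,
        segments=segments,
        genome_fraction=introcall.genome_fraction(segments, chrom_length),
    )


def analyze_pair(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    background_of: dict[str, str],
    outgroup: str,
    chrom_length: int,
    params: ScanParams,
) -> dict:
    """Both flow directions between two focal populations plus their
    bidirectional intersection and the genome-wide D/Z of arrangement 1."""
    windows = make_windows(chrom_length, params.window, params.step, chrom=panel.chrom)
    into_b = scan_direction(
        panel, popmap, pop_a, pop_b, background_of, outgroup, chrom_length, params,
        windows=windows,
    )
    into_a = scan_direction(
        panel, popmap, pop_b, pop_a, background_of, outgroup, chrom_length, params,
        windows=windows,
    )
    both = introcall.intersect_bidirectional(into_b.segments, into_a.segments)
    fq1 = fstats.quartet_freqs(
        panel, popmap, background_of[pop_b], pop_b, pop_a, outgroup
    )
    d_gw = fstats.genomewide_d(fq1)
    d_blocks, spans = fstats.block_d_values(fq1, params.jackknife_block, chrom_length)
    try:
        z = fstats.jackknife_z(d_blocks, spans)
    except InsufficientDataError:
        z = float("nan")
    return {
        "windows": windows,
        "into_b": into_b,
        "into_a": into_a,
        "bidirectional": both,
        "bidirectional_fraction": introcall.genome_fraction(both, chrom_length)
        if both
        else 0.0,
        "d_genomewide": d_gw,
        "z": z,
    }


def truth_union(tracts: list[TruthTract], donor: str | None = None) -> list[tuple[int, int]]:
    spans = [
        (t.start, t.end) for t in tracts if donor is None or t.donor_pop == donor
    ]
    return introcall._union(spans)


def direction_accuracy(
    result: DirectionResult, truth: list[tuple[int, int]], params: ScanParams
) -> float:
    """Fraction of confirmed truth-overlapping candidate windows (top-quantile
    rIBD with positive f_d) assigned this direction; NaN when none qualify."""
    ribd = np.array([rw.ribd for rw in result.ribd_windows], dtype=float)
    try:
        threshold = introcall.top_quantile_threshold(ribd, q=params.q)
    except InsufficientDataError:
        return float("nan")
    n_ok = n_tot = 0
    for rw, f_s, f_o in zip(result.ribd_windows, result.fd_same, result.fd_opp):
        w = rw.window
        if not any(w.start < e and s < w.end for s, e in truth):
            continue
        if np.isnan(rw.ribd) or rw.ribd <= 0 or rw.ribd <= threshold:
            continue
        if np.isnan(f_s) or f_s <= params.fd_min:
            continue
        n_tot += 1
        if introcall.infer_direction(f_s, f_o, delta=params.delta) == introcall.DIR_1:
            n_ok += 1
    return n_ok / n_tot if n_tot else float("nan")


def estimate_alpha(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    donor: str,
    donor_sister: str,
    recipient: str,
    recipient_sister: str,
    outgroup: str,
) -> float:
    """f4-ratio admixture proportion of ``recipient`` ancestry drawn from
    the donor side."""
    freqs = {
        pop: fstats.alt_frequencies(panel, popmap.samples_of(pop))
        for pop in (donor, donor_sister, recipient, recipient_sister, outgroup)
    }
    keep = np.ones(panel.n_sites, dtype=bool)
    for f in freqs.values():
        keep &= ~np.isnan(f)
    return fstats.f4_ratio(
        freqs[donor_sister][keep],
        freqs[outgroup][keep],
        freqs[recipient][keep],
        freqs[donor][keep],
        freqs[recipient_sister][keep],
    )


def run_replicate(
    config: SimulationConfig,
    params: ScanParams | None = None,
    n_svs: int = 0,
    stratified_fraction: float = 0.0,
    co_place: bool = False,
) -> dict:
    """Simulate one replicate and run the full analysis; returns a summary
    dict (JSON-serializable apart from the attached result objects)."""
    params = params or ScanParams()
    panels, tracts = simdata.simulate_history(config)
    panel, popmap = simdata.combined_panel(panels)
    background_of = {"P_A": "W_A", "P_B": "W_B"}
    pair = analyze_pair(
        panel, popmap, "P_A", "P_B", background_of, "OUT",
        config.chromosome_length, params,
    )
    summary: dict = {
        "seed": config.seed,
        "n_sites": panel.n_sites,
        "d_genomewide": pair["d_genomewide"],
        "z": pair["z"],
        "fraction_into_b": pair["into_b"].genome_fraction,
        "fraction_into_a": pair["into_a"].genome_fraction,
        "n_segments_into_b": len(pair["into_b"].segments),
        "n_segments_into_a": len(pair["into_a"].segments),
        "bidirectional_fraction": pair["bidirectional_fraction"],
    }
    if tracts:
        truth_b = truth_union([t for t in tracts if t.recipient_sample.startswith("P_B")])
        truth_a = truth_union([t for t in tracts if t.recipient_sample.startswith("P_A")])
        if truth_b:
            p, r, f1 = introcall.evaluate_recovery(pair["into_b"].segments, truth_b)
            summary["recovery_into_b"] = {"precision": p, "recall": r, "f1": f1}
            summary["direction_accuracy_into_b"] = direction_accuracy(
                pair["into_b"], truth_b, params
            )
        if truth_a:
            p, r, f1 = introcall.evaluate_recovery(pair["into_a"].segments, truth_a)
            summary["recovery_into_a"] = {"precision": p, "recall": r, "f1": f1}
            summary["direction_accuracy_into_a"] = direction_accuracy(
                pair["into_a"], truth_a, params
            )
        summary["alpha_into_b"] = estimate_alpha(
            panel, popmap, "P_A", "W_A", "P_B", "W_B", "OUT"
        )
    if n_svs:
        svs = simdata.simulate_sv_table(
            config, n_svs, stratified_fraction, tracts=tracts, co_place=co_place
        )
        segments = pair["into_b"].segments + pair["into_a"].segments
        calls = svintro.run_sv_scan(
            svs,
            popmap.samples_of("P_A"),
            popmap.samples_of("P_B"),
            segments=segments,
            n_perm=params.n_perm,
            seed=config.seed + 99,
            fst_quantile=params.fst_quantile,
            p_max=params.p_max,
            miss_max=params.miss_max,
            maf_min=params.maf_min,
            max_gap=params.sv_max_gap,
        )
        summary["n_svs"] = len(calls)
        summary["n_specific"] = sum(c.specific for c in calls)
        summary["n_introgressed_svs"] = sum(
            c.classification != "none" for c in calls
        )
        summary["_sv_calls"] = calls
    summary["_pair"] = pair
    summary["_panels"] = panels
    summary["_tracts"] = tracts
    summary["_panel"] = panel
    summary["_popmap"] = popmap
    return summary


def jsonable(summary: dict) -> dict:
    """Strip attached objects and coerce numpy scalars for JSON output."""
    out = {}
    for key, value in summary.items():
        if key.startswith("_"):
            continue
        if isinstance(value, dict):
            out[key] = {k: _scalar(v) for k, v in value.items()}
        else:
            out[key] = _scalar(value)
    return out


def _scalar(x):
    if isinstance(x, (np.floating, np.integer)):
        x = x.item()
    if isinstance(x, float) and (np.isnan(x) or np.isinf(x)):
        return None
    return x
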