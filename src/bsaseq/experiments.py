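"""Validation experiments run against independent oracles and known truth.

Each function here re-derives one whole-pipeline property from scratch —
counting fidelity against a brute-force tally, end-to-end error bounds
against binomial truth, trimming/demultiplexing/merging against exhaustive
oracles, HDI against exhaustive window search, and parameter
recovery/calibration of the hierarchical model under the matched
two-population study design (17 + 30 individuals, 25 CpG sites over four
loci, per-locus depths straddling the 10000/20000/100/500 thresholds).

The oracles are deliberately naive (scalar loops, exhaustive enumeration)
and share no code with the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._rng import substream
from .calling import MethylationMatrix, apply_depth_thresholds, percent_methylation, pileup_cpg_counts
from .model import (
    MCMCSettings,
    build_design,
    contrast_all,
    fit_model,
    hdi,
    prior_predictive,
)
from .pipeline import PipelineConfig, process_read_pairs
from .reads import SequenceRead, demultiplex_by_primer, merge_pairs, quality_trim
from .simulate import (
    IndividualMeta,
    SimulationConfig,
    simulate_cohort,
    simulate_matrix_counts,
    simulate_reads,
)

PAPER_THRESHOLDS = {"ACTB": 10000, "BDNF": 20000, "CRF": 100, "NR3C1": 500}


def _subseed(seed: int, *key) -> int:
    return int(substream(seed, *key).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# 1. Counting oracle


def brute_force_site_tally(
    reads: list[tuple[str, int]], cpg_indices: list[int]
) -> dict[int, dict[str, int]]:
    """Per-column tally over (ref-projected bases, ref_start) pairs.

    Scalar loops only; "-" marks an unaligned (deleted) column and is
    skipped — a read contributes nothing at a site it does not align over.
    """
    tally = {i: {"C": 0, "T": 0, "other": 0} for i in cpg_indices}
    for bases, start in reads:
        for i in cpg_indices:
            k = i - start
            if 0 <= k < len(bases):
                b = bases[k]
                if b == "-":
                    continue
                if b == "C":
                    tally[i]["C"] += 1
                elif b == "T":
                    tally[i]["T"] += 1
                else:
                    tally[i]["other"] += 1
    return tally


def counting_oracle_check(seed: int, n_reads: int = 1000) -> dict:
    """Pileup counts and percent methylation vs a brute-force column tally."""
    cfg = SimulationConfig.default(seed=_subseed(seed, "counting"))
    inds, truth = simulate_cohort(cfg)
    ind = inds[0]
    pcfg = PipelineConfig(seed=cfg.seed)
    per_locus = max(1, n_reads // len(cfg.loci))
    mismatches = 0
    percent_mismatches = 0
    sites_checked = 0
    for locus in cfg.loci:
        pairs = simulate_reads(ind, locus, truth, cfg, n_reads=per_locus)
        alignments, _ = process_read_pairs(pairs, [locus], cfg.primers, pcfg)
        alns = alignments[locus.name]
        counts = pileup_cpg_counts(alns, locus, ind.id)
        # the oracle works in top-strand coordinates from raw aligned
        # strings; this simulator emits top-strand amplicons only
        assert all(a.strand == "OT" for a in alns)
        oracle = brute_force_site_tally(
            [_projected_bases(a) for a in alns], locus.cpg_indices
        )
        for sc, site in zip(counts, locus.cpg_sites):
            o = oracle[site.seq_index]
            sites_checked += 1
            if (sc.n_C, sc.n_T, sc.n_other) != (o["C"], o["T"], o["other"]):
                mismatches += 1
            pct = percent_methylation(sc)
            denom = o["C"] + o["T"]
            expected = None if denom == 0 else 100.0 * o["C"] / denom
            if (pct is None) != (expected is None) or (
                pct is not None and pct != expected
            ):
                percent_mismatches += 1
    return {
        "sites_checked": sites_checked,
        "count_mismatches": mismatches,
        "percent_mismatches": percent_mismatches,
    }


def _projected_bases(aln) -> tuple[str, int]:
    """Read bases laid out in reference order ("-" at deleted columns)."""
    pairs = [
        (int(r), aln.query_bases[k])
        for k, r in enumerate(aln.read_to_ref.tolist())
        if r >= 0
    ]
    start = pairs[0][0]
    out = ["-"] * (pairs[-1][0] - start + 1)
    for r, b in pairs:
        out[r - start] = b
    return "".join(out), start


# ---------------------------------------------------------------------------
# 2. End-to-end fidelity (error-free reads)


def end_to_end_fidelity(seed: int, depth: int = 1000, n_per_population=(2, 2)) -> dict:
    """Error-free full-pipeline percent methylation vs simulated truth.

    With no sequencing error and no conversion failure, every cell must lie
    within 3 binomial standard errors of its truth, and cells whose truth
    is exactly 0 or 1 must come out exactly 0% or 100%.
    """
    baselines_override = {"ACTB:-250": 0.0, "ACTB:-220": 100.0}
    cfg = SimulationConfig.default(seed=_subseed(seed, "fidelity"))
    baselines = dict(cfg.baseline_site_means)
    baselines.update(baselines_override)
    cfg = SimulationConfig.default(
        seed=cfg.seed,
        baseline_site_means=baselines,
        n_per_population=n_per_population,
        individual_sd=0.0,
        conversion_failure_rate=0.0,
        seq_error_rate=0.0,
        depth_per_locus={l: float(depth) for l in PAPER_THRESHOLDS},
        depth_log_sd=0.0,
    )
    inds, truth = simulate_cohort(cfg)
    pcfg = PipelineConfig(seed=cfg.seed)
    n_cells = 0
    n_within = 0
    n_extreme = 0
    n_extreme_exact = 0
    for ind in inds:
        for locus in cfg.loci:
            pairs = simulate_reads(ind, locus, truth, cfg)
            alignments, _ = process_read_pairs(pairs, [locus], cfg.primers, pcfg)
            counts = pileup_cpg_counts(alignments[locus.name], locus, ind.id)
            for sc, site in zip(counts, locus.cpg_sites):
                p = truth.p(ind.id, site.label)
                est = percent_methylation(sc)
                if est is None:
                    continue
                n_cells += 1
                d = sc.informative_depth
                se = 100.0 * math.sqrt(max(p * (1 - p), 1e-12) / d)
                if p in (0.0, 1.0):
                    n_extreme += 1
                    if est == 100.0 * p:
                        n_extreme_exact += 1
                        n_within += 1
                    continue
                if abs(est - 100.0 * p) <= 3.0 * se:
                    n_within += 1
    return {
        "cells": n_cells,
        "pct_within_3se": 100.0 * n_within / n_cells,
        "extreme_cells": n_extreme,
        "pct_extreme_exact": 100.0 * n_extreme_exact / max(n_extreme, 1),
    }


# ---------------------------------------------------------------------------
# 3. Trimming / demultiplexing / merging oracles


def oracle_quality_trim(quals: list[int], end_q: int, window: int, thr: float) -> tuple[int, int]:
    """(start, end) retained span per the trimming rules; scalar loops."""
    lo, hi = 0, len(quals)
    while lo < hi and quals[lo] < end_q:
        lo += 1
    while hi > lo and quals[hi - 1] < end_q:
        hi -= 1
    cut = hi - lo
    for s in range(hi - lo - window + 1):
        if sum(quals[lo + s : lo + s + window]) / window < thr:
            cut = s
            break
    return lo, lo + cut


def trimming_oracle_check(seed: int, n_cases: int = 10000) -> dict:
    rng = substream(seed, "trim-oracle")
    mismatches = 0
    for _ in range(n_cases):
        n = int(rng.integers(0, 60))
        quals = rng.integers(0, 46, size=n)
        bases = "".join(rng.choice(list("ACGT"), size=n))
        read = SequenceRead("r", bases, quals)
        end_q, window, thr = 20, 5, 30.0
        got = quality_trim(read, end_q, window, thr)
        lo, hi = oracle_quality_trim(quals.tolist(), end_q, window, thr)
        if got.bases != bases[lo:hi]:
            mismatches += 1
    return {"cases": n_cases, "trim_mismatches": mismatches}


def oracle_edit_distance_prefix(primer: str, read: str) -> int:
    """min over j of edit_distance(primer, read[:j]); full DP, scalar loops."""
    m = len(primer)
    prev = list(range(m + 1))  # column j=0: delete all of primer
    best = prev[m]
    for ch in read:
        cur = [0] * (m + 1)
        cur[0] = prev[0] + 1  # 5'-anchored: read bases before the primer are edits
        for i in range(1, m + 1):
            cost = 0 if primer[i - 1] == ch else 1
            cur[i] = min(prev[i - 1] + cost, prev[i] + 1, cur[i - 1] + 1)
        best = min(best, cur[m])
        prev = cur
    return best


def oracle_demux(read: str, primers: dict[str, str], rate: float) -> str | None:
    best_locus, best_dist, tie = None, None, False
    for locus, primer in primers.items():
        d = oracle_edit_distance_prefix(primer, read)
        if d > int(rate * len(primer)):
            continue
        if best_dist is None or d < best_dist:
            best_locus, best_dist, tie = locus, d, False
        elif d == best_dist:
            tie = True
    return None if tie else best_locus


def demux_oracle_check(seed: int, n_cases: int = 2000) -> dict:
    rng = substream(seed, "demux-oracle")
    cfg = SimulationConfig.default(seed=0)
    primers = {name: p.forward for name, p in cfg.primers.items()}
    names = list(primers)
    mismatches = 0
    for _ in range(n_cases):
        kind = rng.integers(0, 3)
        insert = "".join(rng.choice(list("ACGT"), size=30))
        if kind == 0:  # random junk
            read = "".join(rng.choice(list("ACGT"), size=50))
        else:  # primer with 0-6 substitutions and possibly an indel
            primer = list(primers[names[rng.integers(0, len(names))]])
            for pos in rng.choice(len(primer), size=rng.integers(0, 7), replace=False):
                primer[pos] = str(rng.choice(list("ACGT")))
            if kind == 2 and len(primer) > 2:
                pos = int(rng.integers(1, len(primer) - 1))
                primer = primer[:pos] + primer[pos + 1 :]  # deletion
            read = "".join(primer) + insert
        got = demultiplex_by_primer(
            SequenceRead("r", read, np.full(len(read), 30)), primers, 0.2
        )
        if got.locus != oracle_demux(read, primers, 0.2):
            mismatches += 1
    return {"cases": n_cases, "demux_mismatches": mismatches}


def merge_exact_check(seed: int, n_cases: int = 500, frag_len: int = 300, read_len: int = 250) -> dict:
    rng = substream(seed, "merge-oracle")
    exact = 0
    for _ in range(n_cases):
        frag = "".join(rng.choice(list("ACGT"), size=frag_len))
        q = np.full(read_len, 38)
        r1 = SequenceRead("p", frag[:read_len], q)
        r2 = SequenceRead("p", frag[-read_len:], q.copy()).reverse_complement()
        merged = merge_pairs(r1, r2)
        if merged is not None and merged.bases == frag:
            exact += 1
    return {"cases": n_cases, "merge_exact_pct": 100.0 * exact / n_cases}


# ---------------------------------------------------------------------------
# 4. HDI oracle


def oracle_hdi(samples: np.ndarray, mass: float) -> tuple[float, float]:
    x = sorted(float(v) for v in np.ravel(samples))
    n = len(x)
    k = max(int(math.ceil(mass * n)), 2)
    best = None
    for i in range(n - k + 1):
        width = x[i + k - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + k - 1])
    return best[1], best[2]


def hdi_oracle_check(seed: int, n_cases: int = 1000, n_normal: int = 100000) -> dict:
    rng = substream(seed, "hdi-oracle")
    mismatches = 0
    for _ in range(n_cases):
        n = int(rng.integers(2, 200))
        kind = rng.integers(0, 3)
        if kind == 0:
            x = rng.normal(size=n)
        elif kind == 1:
            x = rng.exponential(size=n)
        else:
            x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
        mass = float(rng.uniform(0.5, 0.99))
        if hdi(x, mass) != oracle_hdi(x, mass):
            mismatches += 1
    z = rng.standard_normal(n_normal)
    low, high = hdi(z, 0.95)
    return {
        "cases": n_cases,
        "hdi_mismatches": mismatches,
        "normal_low": low,
        "normal_high": high,
    }


# ---------------------------------------------------------------------------
# 5. Study-design parameter recovery


def paper_design_recovery(seed: int, mcmc: MCMCSettings | None = None) -> dict:
    """Recovery of the planted +20/-20 CRF effects under the matched design.

    Simulates the full design (17 + 30 paired individuals, 25 sites over 4
    loci, lognormal depths straddling the per-locus thresholds), filters by
    the thresholds, fits, and summarises which sites' 95% HDIs exclude
    zero.
    """
    cfg = SimulationConfig.default(seed=_subseed(seed, "recovery"))
    inds, truth, matrix = simulate_matrix_counts(cfg)
    filtered = apply_depth_thresholds(matrix, PAPER_THRESHOLDS)
    mcmc = mcmc or MCMCSettings(chains=4, warmup=1000, draws=1000, seed=_subseed(seed, "recovery-mcmc"))
    spec = build_design(filtered, inds, mcmc=mcmc)
    draws = fit_model(spec)
    contrasts = {c.site: c for c in contrast_all(draws)}
    hyper = contrasts["CRF:-101"]
    hypo = contrasts["CRF:-95"]
    null_sites = [s for s in spec.site_labels if s not in ("CRF:-101", "CRF:-95")]
    n_null_zero = sum(
        1 for s in null_sites if contrasts[s].hdi_low <= 0.0 <= contrasts[s].hdi_high
    )
    ba = draws.params["beta_age"].ravel()
    bs = draws.params["beta_sex"]
    beta_sex_contrast = (bs[:, :, 1] - bs[:, :, 0]).ravel() if bs.shape[2] == 2 else bs.ravel()
    return {
        "n_sites": len(spec.site_labels),
        "hyper_mean_delta": hyper.mean,
        "hyper_classified": hyper.classification,
        "hypo_mean_delta": hypo.mean,
        "hypo_classified": hypo.classification,
        "n_null_sites": len(null_sites),
        "n_null_hdi_covering_zero": n_null_zero,
        "beta_age_mean_over_sd": float(abs(ba.mean()) / ba.std()),
        "beta_sex_mean_over_sd": float(abs(beta_sex_contrast.mean()) / beta_sex_contrast.std()),
        "converged": draws.converged,
        "n_excluded_cells": int(filtered.values.isna().sum().sum()),
    }


# ---------------------------------------------------------------------------
# 6. Control-gene null


def control_gene_null(seed: int, n_replicates: int = 20, mcmc: MCMCSettings | None = None) -> dict:
    """Fraction of replicate cohorts where every ACTB site is no_difference.

    The default truth has zero population x site effect at all ACTB sites,
    mirroring the control gene's expected behaviour.
    """
    ok = 0
    for r in range(n_replicates):
        cfg = SimulationConfig.default(seed=_subseed(seed, "null", r))
        inds, truth, matrix = simulate_matrix_counts(cfg)
        filtered = apply_depth_thresholds(matrix, PAPER_THRESHOLDS)
        rep_mcmc = mcmc or MCMCSettings(chains=2, warmup=500, draws=750, seed=_subseed(seed, "null-mcmc", r))
        spec = build_design(filtered, inds, mcmc=rep_mcmc)
        draws = fit_model(spec)
        actb = [c for c in contrast_all(draws) if c.site.startswith("ACTB:")]
        if actb and all(c.classification == "no_difference" for c in actb):
            ok += 1
    return {
        "replicates": n_replicates,
        "all_actb_null_pct": 100.0 * ok / n_replicates,
    }


# ---------------------------------------------------------------------------
# 7. HDI calibration under the model's own prior predictive


def _reduced_spec(seed: int, n_sites: int = 5, n_per_pop: int = 10) -> "object":
    """Complete two-population design matrix skeleton for calibration runs."""
    rng = substream(seed, "calibration-design")
    inds = []
    for p, pop in enumerate(("NRKW", "SRKW")):
        for i in range(n_per_pop):
            inds.append(
                IndividualMeta(
                    f"{pop}_{i:02d}", pop, ("F", "M")[i % 2], float(np.round(rng.uniform(3, 50), 1))
                )
            )
    sites = [f"CRF:{-200 + 10 * s}" for s in range(n_sites)]
    ids = [m.id for m in inds]
    values = pd.DataFrame(50.0, index=ids, columns=sites)
    depth = pd.DataFrame(1000, index=ids, columns=sites)
    locus_depth = pd.DataFrame({"CRF": 1000}, index=ids)
    matrix = MethylationMatrix(values, depth, locus_depth)
    return build_design(matrix, inds)


def calibration_check(seed: int, n_replicates: int = 100, mcmc: MCMCSettings | None = None) -> dict:
    """95% HDI coverage of the per-site contrast over prior-predictive data."""
    base = _reduced_spec(_subseed(seed, "calibration"))
    covered = 0
    total = 0
    for r in range(n_replicates):
        truth, spec = prior_predictive(base, _subseed(seed, "calib-rep", r))
        spec.mcmc = mcmc or MCMCSettings(chains=2, warmup=400, draws=600, seed=_subseed(seed, "calib-mcmc", r))
        draws = fit_model(spec)
        for s, site in enumerate(spec.site_labels):
            c = hdi(draws.contrast_draws(site).ravel(), 0.95)
            total += 1
            if c[0] <= truth["delta_contrast"][s] <= c[1]:
                covered += 1
    return {
        "replicates": n_replicates,
        "intervals": total,
        "coverage_pct": 100.0 * covered / total,
    }
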