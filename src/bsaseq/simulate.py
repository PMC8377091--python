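"""Synthetic two-population bisulfite amplicon cohort with known truth.

Emulates the study design the pipeline targets: two killer-whale
populations (SRKW focal, NRKW comparison) sampled with a paired design —
for every focal individual, one or two comparison individuals of the same
sex and similar age — four promoter amplicons (*ACTB*, *BDNF*, *CRF*,
*NR3C1*) whose CpG sites sit at negative TSS-relative positions, per-locus
read depths spanning orders of magnitude, imperfect bisulfite conversion,
and sequencing error.

Truth is generated on the percent scale: individual i at site s has

    p_is = clamp01( (delta_s + eta_{pop(i),s} + beta_age*age_i
                     + beta_sex(sex_i) + u_i) / 100 ),  u_i ~ N(0, sd_ind)

Methylation is then simulated per read per site independently; the
downstream statistic is a per-site proportion, so within-molecule
correlation would not change anything it measures.

Two generation routes exist: full paired-end FASTQ (exercises every read
processing stage) and a direct counts route that samples per-site
C/T/other counts from the same per-read emission probabilities — the two
agree in distribution, and the counts route makes deep-coverage designs
cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .calling import MethylationMatrix
from .reads import SequenceRead
from .reference import (
    PrimerPair,
    ReferenceLocus,
    bisulfite_convert,
    reverse_complement,
)

__all__ = [
    "IndividualMeta",
    "QualityModel",
    "SimulationConfig",
    "TruthTable",
    "default_loci",
    "simulate_cohort",
    "simulate_reads",
    "simulate_matrix_counts",
    "write_truth",
    "read_truth",
    "write_sample_sheet",
    "read_sample_sheet",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_x] = _y
_IDX_LUT = np.zeros(256, dtype=np.uint8)
for _i, _x in enumerate(b"ACGT"):
    _IDX_LUT[_x] = _i


@dataclass(frozen=True)
class IndividualMeta:
    id: str
    population: str
    sex: str  # "F" or "M"
    age: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class QualityModel:
    """High-quality core with a lower-quality 3' tail, small integer jitter."""

    core_q: int = 38
    tail_q: int = 25
    tail_len: int = 6
    jitter: int = 2


@dataclass
class TruthTable:
    """Ground-truth methylation probabilities: individuals x site labels."""

    probs: pd.DataFrame  # index: individual id; columns: "locus:pos"; values in [0,1]
    meta: list[IndividualMeta] = field(default_factory=list)

    def p(self, individual: str, site_label: str) -> float:
        return float(self.probs.loc[individual, site_label])


@dataclass
class SimulationConfig:
    """Full generative truth for a synthetic cohort.

    The first population is the focal one (the paired design indexes on
    it); ``sex_effect`` is the shift applied to males relative to females.
    ``population_site_deltas`` maps (population, site_label) to a percent
    shift — the default plants +20/-20 at the two CRF sites (-101 / -95)
    and nothing anywhere else.
    """

    loci: list[ReferenceLocus]
    primers: dict[str, PrimerPair]
    baseline_site_means: dict[str, float]
    depth_per_locus: dict[str, float]
    populations: tuple[str, str] = ("SRKW", "NRKW")
    n_per_population: tuple[int, int] = (17, 30)
    pairing: bool = True
    population_site_deltas: dict[tuple[str, str], float] = field(default_factory=dict)
    age_effect: float = 0.0
    sex_effect: float = 0.0
    individual_sd: float = 5.0
    residual_sd_per_population: dict[str, float] = field(default_factory=dict)
    conversion_failure_rate: float = 0.01
    seq_error_rate: float = 0.001
    depth_log_sd: float = 0.5
    read_length: int = 250
    quality_model: QualityModel = field(default_factory=QualityModel)
    overlapping_pairs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("conversion_failure_rate", self.conversion_failure_rate),
            ("seq_error_rate", self.seq_error_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if min(self.n_per_population) < 1:
            raise ValueError("n_per_population must be >= 1 in both populations")
        missing = [l.name for l in self.loci if l.name not in self.depth_per_locus]
        if missing:
            raise ValueError(f"no depth configured for loci {missing}")

    @property
    def site_labels(self) -> list[str]:
        return [lab for locus in self.loci for lab in locus.site_labels]

    @classmethod
    def read_level(cls, seed: int = 0, mean_depth: float = 60.0, **overrides) -> "SimulationConfig":
        """Desk-scale read-level profile: uniform modest per-locus depths.

        The study-scale default depths (10^2-10^4 per locus) are meant for
        the counts route; simulating every read at those depths is
        needlessly heavy for demonstrations, so this profile trades depth
        for run time while keeping every processing stage exercised. Pair
        it with correspondingly small depth thresholds.
        """
        cfg = cls.default(seed=seed)
        cfg = replace(cfg, depth_per_locus={l.name: float(mean_depth) for l in cfg.loci})
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        loci, primers = default_loci()
        baselines = _default_baselines(loci)
        cfg = cls(
            loci=loci,
            primers=primers,
            baseline_site_means=baselines,
            depth_per_locus={"ACTB": 15000.0, "BDNF": 25000.0, "CRF": 300.0, "NR3C1": 800.0},
            population_site_deltas={("SRKW", "CRF:-101"): 20.0, ("SRKW", "CRF:-95"): -20.0},
            residual_sd_per_population={"SRKW": 5.0, "NRKW": 5.0},
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Default reference loci

_LOCUS_SITES = {
    "ACTB": (-250, -220, -180, -150, -120, -80),
    "BDNF": (-260, -230, -200, -170, -140, -110, -75),
    "CRF": (-240, -210, -180, -150, -101, -95, -60),
    "NR3C1": (-230, -190, -155, -120, -85),
}
_LOCUS_LEN = 300
_PRIMER_LEN = 20
_LOCI_BUILD_SEED = 715204663  # fixed: reference sequences are data, not random per run


def _default_baselines(loci: list[ReferenceLocus]) -> dict[str, float]:
    cycle = (35.0, 50.0, 65.0, 45.0, 60.0, 40.0, 55.0)
    out = {}
    k = 0
    for locus in loci:
        for lab in locus.site_labels:
            out[lab] = cycle[k % len(cycle)]
            k += 1
    out["CRF:-101"] = 40.0  # +20 in SRKW keeps the mean well inside (0, 100)
    out["CRF:-95"] = 60.0
    return out


def _build_locus(name: str, tss_positions: tuple[int, ...], rng: np.random.Generator) -> ReferenceLocus:
    L = _LOCUS_LEN
    arr = rng.choice(np.frombuffer(b"ATG", dtype=np.uint8), size=L)
    planted = [L + p for p in tss_positions]
    blocked = set()
    for i in planted:
        arr[i] = ord("C")
        arr[i + 1] = ord("G")
        blocked.update((i, i + 1))
    candidates = [
        i
        for i in range(L)
        if i not in blocked and (i == L - 1 or (arr[i + 1] != ord("G") and i + 1 not in blocked))
    ]
    extra = rng.choice(candidates, size=L // 8, replace=False)
    arr[extra] = ord("C")
    locus = ReferenceLocus(name=name, sequence=arr.tobytes().decode(), tss_index=L)
    got = [s.tss_position for s in locus.cpg_sites]
    if got != sorted(tss_positions):
        raise AssertionError(f"locus construction for {name} produced sites {got}")
    return locus


def default_loci() -> tuple[list[ReferenceLocus], dict[str, PrimerPair]]:
    """The four default promoter amplicons and their primer pairs.

    25 CpG sites across ACTB (6), BDNF (7), CRF (7, including -101 and
    -95) and NR3C1 (5); 300 bp each, TSS just past the amplicon so every
    site is upstream (negative). Primers are the terminal 20-mers of the
    fully converted top strand, CpG-free by construction.
    """
    loci = []
    primers = {}
    for name, sites in _LOCUS_SITES.items():
        rng = substream(_LOCI_BUILD_SEED, "locus", name)
        locus = _build_locus(name, sites, rng)
        conv = bisulfite_convert(locus.sequence)
        primers[name] = PrimerPair(
            locus=name,
            forward=conv[:_PRIMER_LEN],
            reverse=reverse_complement(conv[-_PRIMER_LEN:]),
        )
        loci.append(locus)
    return loci, primers


# ---------------------------------------------------------------------------
# Cohort truth


def _clamp01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def simulate_cohort(config: SimulationConfig) -> tuple[list[IndividualMeta], TruthTable]:
    """Draw cohort metadata and per-(individual, site) truth probabilities.

    With pairing on, each focal-population individual is matched by one or
    two comparison individuals of the same sex and similar age (Gaussian
    age jitter, SD 1.5 years), reproducing a matched sampling design.
    """
    rng = substream(config.seed, "cohort")
    focal_pop, comp_pop = config.populations
    n_focal, n_comp = config.n_per_population
    individuals: list[IndividualMeta] = []
    focal_ages = rng.uniform(3.0, 50.0, size=n_focal)
    focal_sexes = [("F", "M")[i % 2] for i in range(n_focal)]
    for i in range(n_focal):
        individuals.append(
            IndividualMeta(f"{focal_pop}_{i + 1:02d}", focal_pop, focal_sexes[i], round(float(focal_ages[i]), 1))
        )
    if config.pairing:
        base, rem = divmod(n_comp, n_focal)
        k = 0
        for i in range(n_focal):
            n_partners = base + (1 if i < rem else 0)
            for _ in range(n_partners):
                age = float(np.clip(focal_ages[i] + rng.normal(0.0, 1.5), 0.5, None))
                k += 1
                individuals.append(
                    IndividualMeta(f"{comp_pop}_{k:02d}", comp_pop, focal_sexes[i], round(age, 1))
                )
    else:
        comp_ages = rng.uniform(3.0, 50.0, size=n_comp)
        for i in range(n_comp):
            individuals.append(
                IndividualMeta(
                    f"{comp_pop}_{i + 1:02d}", comp_pop, ("F", "M")[i % 2], round(float(comp_ages[i]), 1)
                )
            )

    labels = config.site_labels
    delta = np.array([config.baseline_site_means[lab] for lab in labels])
    u = rng.normal(0.0, config.individual_sd, size=len(individuals))
    rows = {}
    for ind, u_i in zip(individuals, u):
        eta = np.array(
            [config.population_site_deltas.get((ind.population, lab), 0.0) for lab in labels]
        )
        mean = (
            delta
            + eta
            + config.age_effect * ind.age
            + (config.sex_effect if ind.sex == "M" else 0.0)
            + u_i
        )
        rows[ind.id] = _clamp01(mean / 100.0)
    probs = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    return individuals, TruthTable(probs=probs, meta=individuals)


# ---------------------------------------------------------------------------
# Read simulation


def _emission_probs(p: float, cf: float, e: float) -> tuple[float, float, float]:
    """P(read C), P(read T), P(other) at a CpG site.

    The emitted base is C with probability q = p + (1-p)*cf (methylated, or
    unmethylated but conversion failed) else T; a sequencing error then
    substitutes to each of the three other bases with probability e/3.
    """
    q = p + (1.0 - p) * cf
    p_c = q * (1.0 - e) + (1.0 - q) * (e / 3.0)
    p_t = (1.0 - q) * (1.0 - e) + q * (e / 3.0)
    return p_c, p_t, 1.0 - p_c - p_t


def _draw_depth(rng: np.random.Generator, mean_depth: float, log_sd: float) -> int:
    if mean_depth <= 0:
        return 0
    if log_sd <= 0:
        return int(round(mean_depth))
    mu = np.log(mean_depth) - 0.5 * log_sd**2  # mean of the lognormal = mean_depth
    return int(round(float(rng.lognormal(mu, log_sd))))


def simulate_reads(
    individual: IndividualMeta,
    locus: ReferenceLocus,
    truth: TruthTable,
    config: SimulationConfig,
    n_reads: int | None = None,
) -> list[tuple[SequenceRead, SequenceRead]]:
    """Simulate paired 250+250-style reads for one individual at one locus.

    Each molecule is the top-strand amplicon put through conversion: CpG
    cytosines stay C with the individual's site probability, other
    cytosines stay C only on conversion failure. R1 is the molecule 5'
    prefix, R2 the reverse complement of its 3' suffix; primer bases are
    written verbatim over the read starts (they come from the synthetic
    oligo, not the molecule) and per-base substitution errors apply to
    everything. Deterministic given the config seed.
    """
    rng = substream(config.seed, "reads", individual.id, locus.name)
    if n_reads is None:
        n_reads = _draw_depth(rng, config.depth_per_locus[locus.name], config.depth_log_sd)
    if n_reads == 0:
        return []
    seq = np.frombuffer(locus.sequence.encode(), dtype=np.uint8)
    L = len(seq)
    eff_rl = config.read_length if config.overlapping_pairs else max(L // 2 - 5, 1)
    eff_rl = min(eff_rl, L)
    cpg_idx = np.array(locus.cpg_indices, dtype=np.int64)
    non_cpg_c = np.array(
        [i for i in range(L) if seq[i] == ord("C") and i not in set(locus.cpg_indices)],
        dtype=np.int64,
    )
    template = seq.copy()
    template[non_cpg_c] = ord("T")
    mat = np.tile(template, (n_reads, 1))
    if non_cpg_c.size and config.conversion_failure_rate > 0:
        fail = rng.random((n_reads, non_cpg_c.size)) < config.conversion_failure_rate
        rr, cc = np.nonzero(fail)
        mat[rr, non_cpg_c[cc]] = ord("C")
    if cpg_idx.size:
        p = np.array([truth.p(individual.id, lab) for lab in locus.site_labels])
        meth = rng.random((n_reads, cpg_idx.size)) < p
        block = np.where(meth, ord("C"), ord("T")).astype(np.uint8)
        mat[:, cpg_idx] = block

    pair = config.primers[locus.name]
    fwd = np.frombuffer(pair.forward.encode(), dtype=np.uint8)
    rev = np.frombuffer(pair.reverse.encode(), dtype=np.uint8)
    r1 = mat[:, :eff_rl].copy()
    r1[:, : len(fwd)] = fwd
    r2 = _COMP_LUT[mat[:, L - eff_rl :]][:, ::-1].copy()
    r2[:, : len(rev)] = rev

    e = config.seq_error_rate
    for block in (r1, r2):
        if e > 0:
            mask = rng.random(block.shape) < e
            k = int(mask.sum())
            if k:
                idx = _IDX_LUT[block[mask]]
                block[mask] = _BASES[(idx + rng.integers(1, 4, size=k)) % 4]

    qm = config.quality_model
    out = []
    for strand_block in (r1, r2):
        q = qm.core_q + rng.integers(-qm.jitter, qm.jitter + 1, size=strand_block.shape)
        if qm.tail_len > 0:
            tail = min(qm.tail_len, eff_rl)
            q[:, -tail:] = qm.tail_q + rng.integers(-qm.jitter, qm.jitter + 1, size=(n_reads, tail))
        out.append(np.clip(q, 2, 40))
    q1, q2 = out

    pairs = []
    for k in range(n_reads):
        rid = f"{individual.id}:{locus.name}:{k}"
        pairs.append(
            (
                SequenceRead(rid, r1[k].tobytes().decode(), q1[k]),
                SequenceRead(rid, r2[k].tobytes().decode(), q2[k]),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Direct counts route (no reads)


def simulate_matrix_counts(
    config: SimulationConfig,
    individuals: list[IndividualMeta] | None = None,
    truth: TruthTable | None = None,
) -> tuple[list[IndividualMeta], TruthTable, MethylationMatrix]:
    """Sample the methylation matrix directly from per-site count draws.

    Per (individual, locus): depth ~ lognormal around the configured mean,
    then per site (n_C, n_T, n_other) ~ Multinomial(depth, emission probs)
    with the same emission model the read simulator uses. Equivalent in
    distribution to running error-free geometry through the full read
    pipeline, at a fraction of the cost for deep designs.
    """
    if individuals is None or truth is None:
        individuals, truth = simulate_cohort(config)
    labels = config.site_labels
    values = {}
    site_depth = {}
    locus_depth = {}
    for ind in individuals:
        vrow, drow, lrow = {}, {}, {}
        for locus in config.loci:
            rng = substream(config.seed, "counts", ind.id, locus.name)
            depth = _draw_depth(rng, config.depth_per_locus[locus.name], config.depth_log_sd)
            lrow[locus.name] = depth
            for lab in locus.site_labels:
                if depth == 0:
                    vrow[lab], drow[lab] = np.nan, 0
                    continue
                pc, pt, po = _emission_probs(
                    truth.p(ind.id, lab), config.conversion_failure_rate, config.seq_error_rate
                )
                n_c, n_t, _ = rng.multinomial(depth, [pc, pt, po])
                inf = int(n_c + n_t)
                vrow[lab] = 100.0 * n_c / inf if inf else np.nan
                drow[lab] = inf
        values[ind.id] = vrow
        site_depth[ind.id] = drow
        locus_depth[ind.id] = lrow
    ids = [ind.id for ind in individuals]
    matrix = MethylationMatrix(
        values=pd.DataFrame.from_dict(values, orient="index").reindex(index=ids, columns=labels),
        site_depth=pd.DataFrame.from_dict(site_depth, orient="index")
        .reindex(index=ids, columns=labels)
        .astype(int),
        locus_depth=pd.DataFrame.from_dict(locus_depth, orient="index").reindex(
            index=ids, columns=[l.name for l in config.loci]
        ),
    )
    return individuals, truth, matrix


# ---------------------------------------------------------------------------
# TSV I/O


def write_truth(truth: TruthTable, path: str | Path) -> None:
    meta_by_id = {m.id: m for m in truth.meta}
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\tsex\tage\tsite\tp_true\n")
        for ind_id, row in truth.probs.iterrows():
            m = meta_by_id.get(ind_id)
            pop, sex, age = (m.population, m.sex, repr(m.age)) if m else ("", "", "")
            for site, p in row.items():
                fh.write(f"{ind_id}\t{pop}\t{sex}\t{age}\t{site}\t{float(p)!r}\n")


def read_truth(path: str | Path) -> TruthTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"individual": str, "site": str}, float_precision="round_trip"
    )
    if df.empty:
        return TruthTable(probs=pd.DataFrame(), meta=[])
    probs = df.pivot(index="individual", columns="site", values="p_true")
    probs = probs.reindex(index=df["individual"].unique(), columns=df["site"].unique())
    meta = [
        IndividualMeta(r.individual, r.population, r.sex, float(r.age))
        for r in df.drop_duplicates("individual").itertuples()
    ]
    return TruthTable(probs=probs, meta=meta)


def write_sample_sheet(
    individuals: list[IndividualMeta],
    path: str | Path,
    fastq_paths: dict[str, tuple[str, str]] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tpopulation\tsex\tage\tfastq_1\tfastq_2\n")
        for ind in individuals:
            f1, f2 = (fastq_paths or {}).get(ind.id, ("", ""))
            fh.write(f"{ind.id}\t{ind.population}\t{ind.sex}\t{ind.age}\t{f1}\t{f2}\n")


def read_sample_sheet(path: str | Path) -> tuple[list[IndividualMeta], dict[str, tuple[str, str]]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "population", "sex", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    individuals = []
    fastqs = {}
    for r in df.itertuples():
        individuals.append(IndividualMeta(r.id, r.population, r.sex, float(r.age)))
        f1 = getattr(r, "fastq_1", "") or ""
        f2 = getattr(r, "fastq_2", "") or ""
        if isinstance(f1, float):
            f1 = ""
        if isinstance(f2, float):
            f2 = ""
        fastqs[r.id] = (f1, f2)
    return individuals, fastqs
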