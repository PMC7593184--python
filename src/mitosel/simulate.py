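"""Synthetic experimental-evolution data generator.

Emulates the statistical structure of a replicated mitochondrial
haplotype-competition experiment: three maternally inherited haplotypes
started at frequency 1/3 in each line, selection plus drift on the
maternal (female) lineage pool, pool-seq read counts with per-gene
mapping bias, and lifetime-reproductive-success (LRS) phenotypes.

The default parameters mirror the study design this package analyzes:
24 lines (3 nuclear backgrounds x 2 thermal regimes x 2 maternal-Eve
replicates x 2 technical replicates, one Yemen/35C line lost, leaving
23), 36 generations at 35C and 23 at 23C, pools of 100 individuals,
13 protein-coding genes, and ~12,000 informative reads per sample
(about 60x effective mitogenome coverage).
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    GENERATIONS_BY_REGIME,
    HAPLOTYPES,
    NATIVE_HAPLOTYPE,
    NUCLEAR_BACKGROUNDS,
    PCG_NAMES,
    THERMAL_REGIMES,
)

__all__ = [
    "SimulationParams",
    "full_design",
    "default_fitness_map",
    "simulate_wf_trajectory",
    "simulate_poolseq_counts",
    "simulate_control_samples",
    "simulate_lrs",
    "simulate_experiment",
    "ExperimentBundle",
    "line_rng",
    "synthetic_mitogenomes",
]

_UNIFORM = np.full(3, 1.0 / 3.0)


def _check_composition(freq, name: str = "composition") -> np.ndarray:
    freq = np.asarray(freq, dtype=float)
    if freq.shape != (3,):
        raise ValueError(f"{name} must have exactly 3 components, got shape {freq.shape}")
    if np.any(freq < 0):
        raise ValueError(f"{name} has negative components: {freq}")
    if abs(freq.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {freq.sum():.12f})")
    return freq


@dataclass
class SimulationParams:
    """Parameters of the synthetic experiment.

    Attributes
    ----------
    n_females:
        Effective size of the maternally transmitted pool; drift acts on
        this many lineages each generation (mtDNA is maternally
        inherited). Default 300, about half of the ~600 adults kept per
        line.
    pool_size:
        Number of individuals pooled for sequencing (default 100).
    total_reads:
        Expected informative reads per sample, split evenly across
        genes. Default 12,000, calibrated to ~60x effective coverage of
        a beetle mitogenome at zero-mismatch mapping.
    bias_factors:
        (n_genes, 3) positive multipliers on the read-sampling
        probability of each haplotype in each gene; 1.0 = unbiased.
    deterministic_mode:
        If True, bypass drift, pool sampling and read noise: the
        trajectory follows the infinite-population recursion and read
        "counts" are exact expectations.
    """

    n_females: int = 300
    w_true: dict[tuple[str, str], np.ndarray] = field(default_factory=lambda: default_fitness_map())
    pool_size: int = 100
    genes: tuple[str, ...] = PCG_NAMES
    total_reads: float = 12_000.0
    bias_factors: np.ndarray | None = None
    seed: int = 0
    deterministic_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_females <= 0:
            raise ValueError("n_females must be positive")
        if self.pool_size <= 0:
            raise ValueError("pool_size must be positive")
        if self.pool_size > 2 * self.n_females:
            raise ValueError("pool_size exceeds the census size implied by n_females")
        if self.bias_factors is None:
            self.bias_factors = np.ones((self.n_genes, 3))
        self.bias_factors = np.asarray(self.bias_factors, dtype=float)
        if self.bias_factors.shape != (self.n_genes, 3):
            raise ValueError(
                f"bias_factors must have shape ({self.n_genes}, 3), got {self.bias_factors.shape}"
            )
        if np.any(self.bias_factors <= 0):
            raise ValueError("bias factors must be strictly positive")
        for key, w in self.w_true.items():
            w = np.asarray(w, dtype=float)
            if np.any(w <= 0):
                raise ValueError(f"fitness values must be positive (cell {key}: {w})")
            self.w_true[key] = w

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def reads_per_gene(self) -> float:
        return self.total_reads / self.n_genes

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)


def default_fitness_map() -> dict[tuple[str, str], np.ndarray]:
    """Per-(thermal, nuclear) true relative fitness of (BRA, CAL, YEM).

    Encodes the qualitative structure recovered by the analysis this
    generator feeds: CAL fittest overall, YEM least fit; CAL and YEM
    relatively fitter at 35C than 23C while BRA shows the opposite; and
    a native-background (mitonuclear) bonus at 35C, with BRA alone
    keeping its native advantage at 23C. Magnitudes are ~1% per
    generation, the scale at which end-point frequencies move a few
    percent per decade of generations.
    """

    base = {
        "35C": np.array([0.996, 1.012, 0.993]),
        "23C": np.array([1.003, 1.006, 0.988]),
    }
    native_bonus = {"35C": 0.004, "23C": 0.0}
    bra_cold_bonus = 0.004
    out: dict[tuple[str, str], np.ndarray] = {}
    for thermal in THERMAL_REGIMES:
        for nuclear in NUCLEAR_BACKGROUNDS:
            w = base[thermal].copy()
            native = HAPLOTYPES.index(NATIVE_HAPLOTYPE[nuclear])
            w[native] += native_bonus[thermal]
            if thermal == "23C" and nuclear == "Brazil":
                w[HAPLOTYPES.index("BRA")] += bra_cold_bonus
            out[(thermal, nuclear)] = w
    return out


def full_design(missing_lines: tuple[str, ...] = ("Yemen-35C-e2t2",)) -> pd.DataFrame:
    """The 3 x 2 x 2 x 2 = 24-line design table, minus lost lines.

    By default one Yemen-background 35C replicate is dropped,
    reproducing the realized 23-line design.
    """

    rows = []
    for nuclear in NUCLEAR_BACKGROUNDS:
        for thermal in THERMAL_REGIMES:
            for eve in (1, 2):
                for tech in (1, 2):
                    line_id = f"{nuclear}-{thermal}-e{eve}t{tech}"
                    rows.append(
                        {
                            "line_id": line_id,
                            "nuclear": nuclear,
                            "thermal": thermal,
                            "eve": eve,
                            "tech": tech,
                            "generations": GENERATIONS_BY_REGIME[thermal],
                        }
                    )
    design = pd.DataFrame(rows)
    missing = set(missing_lines)
    unknown = missing - set(design["line_id"])
    if unknown:
        raise ValueError(f"missing_lines not in design: {sorted(unknown)}")
    return design[~design["line_id"].isin(missing)].reset_index(drop=True)


def line_rng(seed: int, line_id: str) -> np.random.Generator:
    """Deterministic per-line random stream derived from (seed, line_id)."""

    return np.random.default_rng([seed, zlib.crc32(line_id.encode())])


def simulate_wf_trajectory(
    start,
    w,
    t: int,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Haploid Wright-Fisher trajectory under constant selection.

    Each generation applies the selection recursion
    ``p_i' = p_i W_i / sum_j p_j W_j`` and then, unless
    ``params.deterministic_mode``, resamples the composition as a
    multinomial draw of ``n_females`` maternal lineages divided by
    ``n_females``.

    Returns an array of shape (t + 1, 3) including the start.
    """

    start = _check_composition(start, "start")
    w = np.asarray(w, dtype=float)
    if w.shape != (3,):
        raise ValueError("w must have 3 components")
    if np.any(w <= 0):
        raise ValueError(f"fitness values must be strictly positive, got {w}")
    if t < 0:
        raise ValueError("t must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    traj = np.empty((t + 1, 3))
    traj[0] = start
    p = start.copy()
    for gen in range(1, t + 1):
        p = p * w
        p /= p.sum()
        if not params.deterministic_mode:
            counts = rng.multinomial(params.n_females, p)
            p = counts / params.n_females
        traj[gen] = p
    return traj


def simulate_poolseq_counts(
    composition,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
    skip_pool: bool = False,
    is_control: bool = False,
) -> pd.DataFrame:
    """Pool-seq read counts for one sample, long format.

    Two-stage sampling: (1) a pool of ``pool_size`` individuals is
    drawn multinomially from the line's haplotype composition; (2) per
    gene, a Poisson total read count (mean ``reads_per_gene``) is
    allocated multinomially with probabilities proportional to
    pool fraction x bias factor. ``skip_pool`` uses the composition
    itself as the pool (exactly known frequencies, as in control
    samples pooled from pure lines).
    """

    composition = _check_composition(composition)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.reads_per_gene <= 0:
        warnings.warn(f"zero coverage for sample {sample_id!r}: emitting empty counts")
        return pd.DataFrame(columns=["sample_id", "gene", "haplotype", "reads", "is_control"])

    if skip_pool or params.deterministic_mode:
        pool_frac = composition
    else:
        pool = rng.multinomial(params.pool_size, composition)
        pool_frac = pool / params.pool_size

    rows = []
    for g, gene in enumerate(params.genes):
        probs = pool_frac * params.bias_factors[g]
        total = probs.sum()
        if total == 0:
            reads = np.zeros(3, dtype=int)
        else:
            probs = probs / total
            if params.deterministic_mode:
                # exact expected reads (float), so downstream proportion
                # estimates are exact oracles rather than rounded counts
                reads = params.reads_per_gene * probs
            else:
                n_reads = rng.poisson(params.reads_per_gene)
                reads = rng.multinomial(n_reads, probs)
        for h, hap in enumerate(HAPLOTYPES):
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": gene,
                    "haplotype": hap,
                    "reads": float(reads[h]) if params.deterministic_mode else int(reads[h]),
                    "is_control": is_control,
                }
            )
    return pd.DataFrame(rows)


def simulate_control_samples(
    n: int,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """``n`` control samples at exactly known composition (1/3, 1/3, 1/3).

    Controls are pooled from pure lines in equal numbers, so the pool
    composition is exact and pool sampling is skipped; read sampling
    (with the configured bias factors) still applies.
    """

    if n < 1:
        raise ValueError("need at least one control sample")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    frames = [
        simulate_poolseq_counts(
            _UNIFORM,
            params,
            rng,
            sample_id=f"control{i + 1}",
            skip_pool=True,
            is_control=True,
        )
        for i in range(n)
    ]
    return pd.concat(frames, ignore_index=True)


def simulate_lrs(
    lines: pd.DataFrame,
    haplotype_effects: dict[str, float],
    compositions: dict[tuple[str, int], np.ndarray] | None,
    n_assays: int = 19,
    rng: np.random.Generator | None = None,
    generations: tuple[int, int] = (3, 33),
    base_log_eggs: float = 4.0,
    sex_effect: float = 0.15,
    generation_effect: float = -0.05,
    line_sd: float = 0.08,
    residual_sd: float = 0.35,
    seed: int | None = None,
) -> pd.DataFrame:
    """Lifetime-reproductive-success assays with log-normal egg counts.

    ``lines`` needs columns line_id, line_type (mix|pure), nuclear; pure
    lines carry the native haplotype of their nuclear background. The
    mean log egg count of a mix line is the composition-weighted mean of
    per-haplotype effects (composition taken from ``compositions`` at
    the assay generation, defaulting to uniform 1/3), plus line, sex and
    generation terms. Female assays house two females, so their egg
    counts are halved into ``adjusted_eggs`` to be comparable with the
    single-male assays.
    """

    if n_assays < 1:
        raise ValueError("n_assays must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    effects = np.array([haplotype_effects.get(h, 0.0) for h in HAPLOTYPES])

    rows = []
    for rec in lines.itertuples(index=False):
        line_intercept = rng.normal(0.0, line_sd)
        for gen in generations:
            if rec.line_type == "pure":
                comp = np.zeros(3)
                comp[HAPLOTYPES.index(NATIVE_HAPLOTYPE[rec.nuclear])] = 1.0
            elif compositions is not None and (rec.line_id, gen) in compositions:
                comp = _check_composition(compositions[(rec.line_id, gen)])
            else:
                comp = _UNIFORM
            mito_effect = float(comp @ effects)
            for sex in ("female", "male"):
                mu = (
                    base_log_eggs
                    + line_intercept
                    + mito_effect
                    + (sex_effect if sex == "female" else 0.0)
                    + (generation_effect if gen == generations[1] else 0.0)
                )
                log_counts = rng.normal(mu, residual_sd, size=n_assays)
                eggs = np.round(np.exp(log_counts)).astype(int)
                for e in eggs:
                    rows.append(
                        {
                            "line_id": rec.line_id,
                            "line_type": rec.line_type,
                            "nuclear": rec.nuclear,
                            "sex": sex,
                            "generation": gen,
                            "fertile_eggs": int(e),
                            "adjusted_eggs": e / 2.0 if sex == "female" else float(e),
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class ExperimentBundle:
    """Everything one synthetic experiment produces."""

    design: pd.DataFrame
    counts: pd.DataFrame  # mix-line samples + control samples, long format
    phenotypes: pd.DataFrame
    true_w: dict[str, np.ndarray]  # line_id -> planted (BRA, CAL, YEM) fitness
    true_compositions: dict[str, np.ndarray]  # line_id -> final composition
    params: SimulationParams


def simulate_experiment(
    params: SimulationParams | None = None,
    seed: int | None = None,
    n_controls: int = 3,
    design: pd.DataFrame | None = None,
    lrs_haplotype_effects: dict[str, float] | None = None,
    n_assays: int = 19,
) -> ExperimentBundle:
    """Simulate the full experiment: trajectories, pool-seq and LRS.

    One sample is sequenced per line at its end point; ``n_controls``
    control samples at known 1/3 frequencies are added. LRS assays are
    run for the 35C mix lines and matching pure lines at generations 3
    and 33, with per-haplotype reproductive effects defaulting to a CAL
    advantage and YEM disadvantage concordant with the planted fitness.
    """

    if params is None:
        params = SimulationParams()
    if seed is not None:
        params = params.replace(seed=seed)
    if design is None:
        design = full_design()
    if lrs_haplotype_effects is None:
        lrs_haplotype_effects = {"BRA": 0.0, "CAL": 0.08, "YEM": -0.08}

    count_frames = []
    true_w: dict[str, np.ndarray] = {}
    true_comp: dict[str, np.ndarray] = {}
    compositions_at: dict[tuple[str, int], np.ndarray] = {}
    for rec in design.itertuples(index=False):
        rng = line_rng(params.seed, rec.line_id)
        w = params.w_true[(rec.thermal, rec.nuclear)]
        traj = simulate_wf_trajectory(_UNIFORM, w, int(rec.generations), params, rng)
        true_w[rec.line_id] = w
        true_comp[rec.line_id] = traj[-1]
        for gen in (3, 33):
            if gen <= rec.generations:
                compositions_at[(rec.line_id, gen)] = traj[gen]
        count_frames.append(
            simulate_poolseq_counts(traj[-1], params, rng, sample_id=rec.line_id)
        )
    controls = simulate_control_samples(
        n_controls, params, np.random.default_rng([params.seed, 0xC0])
    )
    counts = pd.concat(count_frames + [controls], ignore_index=True)

    hot_mix = design[design["thermal"] == "35C"][["line_id", "nuclear"]].copy()
    hot_mix["line_type"] = "mix"
    pure_rows = []
    for nuclear in NUCLEAR_BACKGROUNDS:
        pure_rows.append(
            {"line_id": f"{nuclear}-pure", "nuclear": nuclear, "line_type": "pure"}
        )
    lrs_lines = pd.concat([hot_mix, pd.DataFrame(pure_rows)], ignore_index=True)
    phenotypes = simulate_lrs(
        lrs_lines,
        lrs_haplotype_effects,
        compositions_at,
        n_assays=n_assays,
        rng=np.random.default_rng([params.seed, 0xE66]),
    )
    return ExperimentBundle(
        design=design,
        counts=counts,
        phenotypes=phenotypes,
        true_w=true_w,
        true_compositions=true_comp,
        params=params,
    )


# ---------------------------------------------------------------------------
# Synthetic mitogenomes (for the divergence stage)
# ---------------------------------------------------------------------------


def synthetic_mitogenomes(
    seed: int = 0,
    codon_range: tuple[int, int] = (60, 110),
    syn_per_hap: tuple[int, int, int] = (6, 4, 10),
    nonsyn_per_hap: tuple[int, int, int] = (2, 1, 3),
    intergenic_snps: int = 3,
    deletion: bool = True,
):
    """Three synthetic mitogenomes with planted, known divergence.

    Generates a reference-style genome of 13 protein-coding genes
    (a few on the minus strand) separated by short intergenic spacers,
    then derives three haplotypes (BRA, CAL, YEM) by planting
    substitutions unique to each haplotype: ``syn_per_hap[k]``
    synonymous and ``nonsyn_per_hap[k]`` nonsynonymous coding changes
    (verified against the invertebrate mitochondrial code), plus
    ``intergenic_snps`` spacer substitutions (round-robin across
    haplotypes) and, optionally, one single-base deletion in a spacer
    of the YEM haplotype. Returns ``(genomes, truth)`` where ``truth``
    records the planted counts.
    """

    from Bio.Seq import Seq

    from .constants import INVERTEBRATE_MITO_TABLE
    from .divergence import CdsFeature, MitoGenome

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    stops = {"TAA", "TAG"}
    minus_genes = {"nad1", "nad4", "nad4l", "nad5"}

    def translate(codon: str) -> str:
        return str(Seq(codon).translate(table=INVERTEBRATE_MITO_TABLE))

    def random_codon() -> str:
        while True:
            c = "".join(rng.choice(bases, size=3))
            if c not in stops:
                return c

    genes_coding: dict[str, list[str]] = {}
    for gene in PCG_NAMES:
        n_codons = int(rng.integers(codon_range[0], codon_range[1] + 1))
        codons = ["ATG"] + [random_codon() for _ in range(n_codons - 2)] + ["TAA"]
        genes_coding[gene] = codons

    spacers = [
        "".join(rng.choice(bases, size=int(rng.integers(15, 31))))
        for _ in range(len(PCG_NAMES) + 1)
    ]

    hap_ids = list(HAPLOTYPES)
    hap_genes = {h: {g: list(c) for g, c in genes_coding.items()} for h in hap_ids}
    hap_spacers = {h: list(spacers) for h in hap_ids}

    used_codons: set[tuple[str, int]] = set()
    truth = {
        "syn": dict(zip(hap_ids, syn_per_hap)),
        "nonsyn": dict(zip(hap_ids, nonsyn_per_hap)),
        "intergenic_snps": intergenic_snps,
        "deletions": 1 if deletion else 0,
    }

    def plant(hap: str, synonymous: bool) -> None:
        for _ in range(10_000):
            gene = str(rng.choice(PCG_NAMES))
            codons = hap_genes[hap][gene]
            ci = int(rng.integers(1, len(codons) - 1))  # skip start and stop
            if (gene, ci) in used_codons:
                continue
            codon = codons[ci]
            aa = translate(codon)
            pos = 2 if synonymous else int(rng.integers(0, 2))
            alts = [b for b in "ACGT" if b != codon[pos]]
            rng.shuffle(alts)
            for b in alts:
                new = codon[:pos] + b + codon[pos + 1 :]
                if new in stops:
                    continue
                if (translate(new) == aa) == synonymous:
                    codons[ci] = new
                    used_codons.add((gene, ci))
                    return
        raise RuntimeError("could not place a planted substitution")

    for k, hap in enumerate(hap_ids):
        for _ in range(syn_per_hap[k]):
            plant(hap, synonymous=True)
        for _ in range(nonsyn_per_hap[k]):
            plant(hap, synonymous=False)

    used_spacer: set[tuple[int, int]] = set()
    for i in range(intergenic_snps):
        hap = hap_ids[i % 3]
        for _ in range(10_000):
            si = int(rng.integers(0, len(spacers)))
            pos = int(rng.integers(0, len(spacers[si])))
            if (si, pos) in used_spacer:
                continue
            used_spacer.add((si, pos))
            old = hap_spacers[hap][si][pos]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            s = hap_spacers[hap][si]
            hap_spacers[hap][si] = s[:pos] + new + s[pos + 1 :]
            break
    if deletion:
        for _ in range(10_000):
            si = int(rng.integers(1, len(spacers) - 1))
            pos = int(rng.integers(0, len(spacers[si])))
            if (si, pos) in used_spacer:
                continue
            used_spacer.add((si, pos))
            s = hap_spacers["YEM"][si]
            hap_spacers["YEM"][si] = s[:pos] + s[pos + 1 :]
            break

    genomes = []
    for hap in hap_ids:
        parts = []
        cds = []
        cursor = 0
        for gi, gene in enumerate(PCG_NAMES):
            sp = hap_spacers[hap][gi]
            parts.append(sp)
            cursor += len(sp)
            coding = "".join(hap_genes[hap][gene])
            if gene in minus_genes:
                segment = str(Seq(coding).reverse_complement())
                strand = "-"
            else:
                segment = coding
                strand = "+"
            parts.append(segment)
            cds.append(CdsFeature(gene=gene, start=cursor, end=cursor + len(segment), strand=strand))
            cursor += len(segment)
        parts.append(hap_spacers[hap][-1])
        genomes.append(MitoGenome(id=hap, sequence="".join(parts), cds=cds))
    return genomes, truth
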