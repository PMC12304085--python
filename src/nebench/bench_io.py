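"""Benchmark orchestration, standard-format I/O and fixture generators.

The benchmark design crosses migration rates {0.01, 0.05, 0.10} (three
replicate simulations each) with twelve data subsets per simulation: locus
counts {1000, 10,000, 30,000} x per-deme sample sizes {14, 50, 56, 140},
drawn only from individuals sampled at the final time step -- 108 subsets in
total, every one reproducible from its (simulation seed, subset seed) pair.
Per-subset estimator failures (including infinite/negative LD estimates) are
recorded as flagged rows, never aborting the sweep, because those outcomes
are results in their own right for large populations.

File formats: genepop (2- or 3-digit diploid codes), VCF 4.2 (1-based
positions, ancestral allele as REF; read back through cyvcf2), PLINK-style
PED+MAP, plus the dadi SFS format in :mod:`nebench.sfs_tools`.  All writers
round-trip their genotype content exactly.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import sfs_tools
from .demography import VitalRates, default_vital_rates, generation_length
from .errors import ConfigError, FormatError, NebenchError
from .forward_sim import NO_PARENT, PedigreeTable, SimConfig, run
from .genome_sim import GenotypeMatrix, subset_loci, simulate_genomes, unlinked_genome_spec
from .ld_ne import estimate_ld_ne

__all__ = [
    "BenchDesign",
    "SubsetSpec",
    "enumerate_design",
    "run_benchmark",
    "write_genepop",
    "read_genepop",
    "write_ped_map",
    "read_ped_map",
    "write_vcf",
    "read_vcf",
    "make_fixtures",
]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchDesign:
    """The full factorial benchmark design (defaults: the 108-subset study)."""

    migration_levels: tuple[float, ...] = (0.01, 0.05, 0.10)
    replicates: int = 3
    locus_counts: tuple[int, ...] = (1000, 10_000, 30_000)
    sample_sizes: tuple[int, ...] = (14, 50, 56, 140)
    sampling_step: int = 100
    base_seed: int = 17

    @property
    def n_simulations(self) -> int:
        return len(self.migration_levels) * self.replicates

    @property
    def subsets_per_simulation(self) -> int:
        return len(self.locus_counts) * len(self.sample_sizes)


@dataclass(frozen=True)
class SubsetSpec:
    subset_id: int
    migration: float
    replicate: int
    sim_seed: int
    n_loci: int
    n_per_deme: int
    subset_seed: int


def enumerate_design(design: BenchDesign) -> list[SubsetSpec]:
    """Deterministic ordered list of subset specifications with unique seeds."""
    n_sims = design.n_simulations
    n_subs = n_sims * design.subsets_per_simulation
    seeds = np.random.SeedSequence(design.base_seed).generate_state(
        n_sims + n_subs
    ) % (2**31)
    specs = []
    sid = 0
    for si, (m, rep) in enumerate(
        itertools.product(design.migration_levels, range(design.replicates))
    ):
        for n_loci, n_samp in itertools.product(
            design.locus_counts, design.sample_sizes
        ):
            specs.append(
                SubsetSpec(
                    subset_id=sid,
                    migration=float(m),
                    replicate=rep,
                    sim_seed=int(seeds[si]),
                    n_loci=int(n_loci),
                    n_per_deme=int(n_samp),
                    subset_seed=int(seeds[n_sims + sid]),
                )
            )
            sid += 1
    return specs


def run_benchmark(
    design: BenchDesign,
    estimators: tuple[str, ...] = ("ld",),
    scale: float = 1.0,
    rates: VitalRates | None = None,
    n_candidate_loci: int | None = None,
    locus_length: float = 2e3,
    mutation_rate: float = 1e-7,
    maf_min: float = 0.05,
    out_dir=None,
) -> pd.DataFrame:
    """Execute simulate -> genomes -> subset -> estimate for every spec.

    ``scale`` shrinks the cohort size (and hence census and Ne) for
    desk-scale runs.  Genomes are generated once per simulation (unlinked
    loci for the individuals sampled at the final step) and re-subset for
    each locus-count/sample-size combination; per-deme estimates are
    produced, matching the study design of one estimate per sub-population.
    Failures become flagged rows.  With ``out_dir`` the per-subset genepop
    files and an incrementally updated ``results.csv`` are persisted, and
    completed (subset, estimator, deme) rows found there are not recomputed.
    """
    if not 0 < scale <= 1:
        raise ConfigError("scale must lie in (0, 1]")
    rates = rates or default_vital_rates()
    T = generation_length(rates)
    specs = enumerate_design(design)
    cohort = max(20, int(round(5000 * scale)))
    done: set[tuple] = set()
    rows: list[dict] = []
    out_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "results.csv"
        if out_path.exists():
            prev = pd.read_csv(out_path)
            rows = prev.to_dict("records")
            done = {
                (r["subset_id"], r["estimator"], r["deme"]) for r in rows
            }

    by_sim: dict[int, list[SubsetSpec]] = {}
    for spec in specs:
        by_sim.setdefault(spec.sim_seed, []).append(spec)

    for sim_seed, sim_specs in by_sim.items():
        todo = [
            s
            for s in sim_specs
            if any(
                (s.subset_id, e, d) not in done
                for e in estimators
                for d in (0, 1)
            )
        ]
        if not todo:
            continue
        m = sim_specs[0].migration
        cfg = SimConfig(
            rates=rates,
            cohort_size=cohort,
            migration=m,
            n_steps=design.sampling_step,
            sampling_start=design.sampling_step - 10,
            sampling_end=design.sampling_step,
            seed=sim_seed,
        )
        sim = run(cfg)
        present = sim.samples[sim.samples.step_sampled == design.sampling_step]
        ids = present.id.to_numpy()
        demes = present.deme.to_numpy()
        n_cand = n_candidate_loci or int(2.0 * max(design.locus_counts))
        gspec = unlinked_genome_spec(
            n_cand,
            locus_length=locus_length,
            mutation_rate=mutation_rate,
            generation_years=T,
        )
        anc_ne = 2.0 * 2772.0 * scale
        rng = np.random.default_rng(sim_seed + 1)
        gm_all = simulate_genomes(
            sim.pedigree, ids, gspec, anc_ne, rng, demes=demes
        )
        for spec in todo:
            srng = np.random.default_rng(spec.subset_seed)
            base = dict(
                subset_id=spec.subset_id,
                migration=spec.migration,
                replicate=spec.replicate,
                n_loci=spec.n_loci,
                n_per_deme=spec.n_per_deme,
            )
            try:
                sub = subset_loci(
                    gm_all, spec.n_loci, maf_min, srng, n_per_deme=spec.n_per_deme
                )
            except NebenchError as exc:
                for est in estimators:
                    for deme in (0, 1):
                        rows.append(
                            base
                            | dict(deme=deme, estimator=est, ne=math.nan,
                                   flag=f"subset-failed: {exc}", runtime=0.0)
                        )
                continue
            if out_dir is not None:
                write_genepop(sub, out_dir / f"subset_{spec.subset_id:03d}.gen")
            for est in estimators:
                for deme in np.unique(sub.demes):
                    key = (spec.subset_id, est, int(deme))
                    if key in done:
                        continue
                    members = np.flatnonzero(sub.demes == deme)
                    one = sub.take_individuals(members)
                    t0 = time.perf_counter()
                    try:
                        if est == "ld":
                            ne = estimate_ld_ne(one, maf_min=maf_min)
                            flag = "" if ne.is_finite else "infinite"
                            val = ne.point
                        elif est == "sfs-watterson":
                            sfs = sfs_tools.compute_sfs(one)
                            ne = sfs_tools.watterson_ne(
                                sfs,
                                mutation_rate,
                                locus_length * n_cand,
                            )
                            flag = ""
                            val = ne.point
                        else:
                            raise ConfigError(f"unknown estimator {est!r}")
                        rows.append(
                            base
                            | dict(deme=int(deme), estimator=est, ne=val,
                                   flag=flag,
                                   runtime=time.perf_counter() - t0)
                        )
                    except NebenchError as exc:
                        rows.append(
                            base
                            | dict(deme=int(deme), estimator=est, ne=math.nan,
                                   flag=f"failed: {exc}",
                                   runtime=time.perf_counter() - t0)
                        )
            if out_path is not None:
                pd.DataFrame(rows).to_csv(out_path, index=False)
    result = pd.DataFrame(rows)
    if out_path is not None:
        result.to_csv(out_path, index=False)
    return result


# ---------------------------------------------------------------------------
# genepop
# ---------------------------------------------------------------------------


def write_genepop(gm: GenotypeMatrix, path, digits: int = 2, title: str | None = None) -> None:
    """Write diploid genotypes in genepop format.

    Allele 1 = ancestral, allele 2 = derived; missing genotypes (< 0)
    become the all-zero code.  One POP block per deme label (single block
    when no labels are attached)."""
    if digits not in (2, 3):
        raise ConfigError("genepop codes use 2 or 3 digits per allele")
    fmt = f"0{digits}d"
    code = {
        0: f"{1:{fmt}}{1:{fmt}}",
        1: f"{1:{fmt}}{2:{fmt}}",
        2: f"{2:{fmt}}{2:{fmt}}",
        -1: "0" * (2 * digits),
    }
    demes = gm.demes if gm.demes is not None else np.zeros(gm.n_individuals, int)
    with open(path, "w") as fh:
        fh.write((title or "nebench simulated genotypes") + "\n")
        for name in gm.locus_names:
            fh.write(f"{name}\n")
        for d in np.unique(demes):
            fh.write("POP\n")
            for i in np.flatnonzero(demes == d):
                geno = " ".join(
                    code[int(g) if g >= 0 else -1] for g in gm.genotypes[i]
                )
                fh.write(f"deme{d}_ind{gm.individuals[i]} , {geno}\n")


def read_genepop(path) -> GenotypeMatrix:
    """Read a genepop file (2- or 3-digit dialect) into a GenotypeMatrix.

    The derived-allele dosage counts the higher allele code; loci carry no
    physical coordinates in this format, so chromosomes/positions are
    filled with locus indices."""
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    if not lines:
        raise FormatError("empty genepop file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        row = lines[i].strip()
        if row:
            # locus names may be comma-separated on one line
            loci.extend([x.strip() for x in row.split(",") if x.strip()])
        i += 1
    if i == len(lines):
        raise FormatError("no POP block found", i)
    genos: list[list[int]] = []
    names: list[str] = []
    demes: list[int] = []
    block = -1
    for ln in range(i, len(lines)):
        row = lines[ln].strip()
        if not row:
            continue
        if row.upper() == "POP":
            block += 1
            continue
        if "," not in row:
            raise FormatError("individual record lacks the comma separator", ln + 1)
        name, geno_str = row.split(",", 1)
        codes = geno_str.split()
        if len(codes) != len(loci):
            raise FormatError(
                f"expected {len(loci)} genotypes, found {len(codes)}", ln + 1
            )
        g_row = []
        for c in codes:
            if len(c) not in (4, 6) or not c.isdigit():
                raise FormatError(f"malformed genotype code {c!r}", ln + 1)
            d = len(c) // 2
            a1, a2 = int(c[:d]), int(c[d:])
            if a1 == 0 or a2 == 0:
                g_row.append(-1)
            else:
                g_row.append(int(a1 == 2) + int(a2 == 2))
        genos.append(g_row)
        names.append(name.strip())
        demes.append(block)
    G = np.asarray(genos, dtype=np.int8)
    return GenotypeMatrix(
        genotypes=G,
        chrom=np.arange(G.shape[1]),
        pos=np.zeros(G.shape[1]),
        individuals=np.array(names),
        demes=np.asarray(demes),
        locus_names=np.array(loci),
    )


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------


def _int_positions(gm: GenotypeMatrix) -> np.ndarray:
    """1-based integer positions, deduplicated within chromosome."""
    pos = np.floor(gm.pos).astype(np.int64) + 1
    out = pos.copy()
    for c in np.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        last = 0
        for i in idx:
            if out[i] <= last:
                out[i] = last + 1
            last = out[i]
    return out


def write_ped_map(gm: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write PLINK-style .ped and .map files (alleles A = ancestral,
    T = derived; missing = 0 0).  MAP rows are sorted by (chromosome,
    position)."""
    if gm.pos is None or gm.chrom is None:
        raise NebenchError("PED/MAP export requires chromosome/position metadata")
    prefix = Path(prefix)
    pos = _int_positions(gm)
    order = np.lexsort((pos, gm.chrom))
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for j in order:
            fh.write(f"{int(gm.chrom[j]) + 1}\t{gm.locus_names[j]}\t0\t{pos[j]}\n")
    allele = {0: "A A", 1: "A T", 2: "T T", -1: "0 0"}
    demes = gm.demes if gm.demes is not None else np.zeros(gm.n_individuals, int)
    with open(ped_path, "w") as fh:
        for i in range(gm.n_individuals):
            geno = " ".join(allele[int(g) if g >= 0 else -1] for g in gm.genotypes[i, order])
            fh.write(
                f"deme{demes[i]} ind{gm.individuals[i]} 0 0 0 -9 {geno}\n"
            )
    return ped_path, map_path


def read_ped_map(prefix) -> GenotypeMatrix:
    """Read the PED/MAP pair written by :func:`write_ped_map`."""
    prefix = Path(prefix)
    chrom, names, pos = [], [], []
    with open(prefix.with_suffix(".map")) as fh:
        for ln, row in enumerate(fh, start=1):
            parts = row.split()
            if len(parts) != 4:
                raise FormatError("MAP rows need 4 columns", ln)
            chrom.append(int(parts[0]) - 1)
            names.append(parts[1])
            pos.append(int(parts[3]) - 1)
    genos, inds, demes = [], [], []
    dose = {("A", "A"): 0, ("A", "T"): 1, ("T", "A"): 1, ("T", "T"): 2,
            ("0", "0"): -1}
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, row in enumerate(fh, start=1):
            parts = row.split()
            alleles = parts[6:]
            if len(alleles) != 2 * len(names):
                raise FormatError("PED genotype count mismatch", ln)
            genos.append(
                [dose[(alleles[2 * j], alleles[2 * j + 1])] for j in range(len(names))]
            )
            demes.append(int(parts[0].removeprefix("deme")))
            inds.append(parts[1].removeprefix("ind"))
    return GenotypeMatrix(
        genotypes=np.asarray(genos, dtype=np.int8),
        chrom=np.asarray(chrom),
        pos=np.asarray(pos, dtype=float),
        individuals=np.array(inds),
        demes=np.asarray(demes),
        locus_names=np.array(names),
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (1-based positions, REF = ancestral allele).

    Phased genotypes are emitted when haplotypes are attached."""
    if gm.pos is None or gm.chrom is None:
        raise NebenchError("VCF export requires chromosome/position metadata")
    pos = _int_positions(gm)
    order = np.lexsort((pos, gm.chrom))
    sep = "|" if gm.haplotypes is not None else "/"
    sample_names = [f"ind{v}" for v in gm.individuals]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=nebench\n")
        for c in np.unique(gm.chrom):
            ln = int(pos[gm.chrom == c].max()) + 1
            fh.write(f"##contig=<ID=chr{int(c) + 1},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for j in order:
            if gm.haplotypes is not None:
                h = gm.haplotypes[:, j]
                gts = [f"{h[2 * i]}{sep}{h[2 * i + 1]}" for i in range(gm.n_individuals)]
            else:
                g2gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
                gts = [g2gt[int(g) if g >= 0 else -1] for g in gm.genotypes[:, j]]
            fh.write(
                f"chr{int(gm.chrom[j]) + 1}\t{pos[j]}\t{gm.locus_names[j]}\t"
                f"A\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (dosage of the ALT allele) using
    cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    chrom, pos, names, rows, haps = [], [], [], [], []
    phased_all = True
    for var in vcf:
        chrom.append(int(var.CHROM.removeprefix("chr")) - 1)
        pos.append(var.POS - 1)
        names.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        g_row, h_row = [], []
        for g in var.genotypes:
            a1, a2, phased = g[0], g[1], bool(g[2])
            phased_all &= phased
            if a1 < 0 or a2 < 0:
                g_row.append(-1)
                h_row.extend([-1, -1])
            else:
                g_row.append(a1 + a2)
                h_row.extend([a1, a2])
        rows.append(g_row)
        haps.append(h_row)
    inds = [s.removeprefix("ind") for s in vcf.samples]
    vcf.close()
    G = np.asarray(rows, dtype=np.int8).T
    H = np.asarray(haps, dtype=np.int8).T if phased_all else None
    return GenotypeMatrix(
        genotypes=G,
        chrom=np.asarray(chrom),
        pos=np.asarray(pos, dtype=float),
        individuals=np.array(inds),
        haplotypes=H,
        locus_names=np.array(names),
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _wf_genotypes(n: int, loci: int, gens: int, rng) -> np.ndarray:
    """Discrete-generation Wright-Fisher genotypes with unlinked loci.

    Initialised at linkage equilibrium (frequencies uniform on [0.1, 0.9])
    and evolved ``gens`` generations with random union of gametes, which
    re-establishes the drift LD equilibrium E[r2] ~ 1/(3N) within a few
    generations at free recombination."""
    f = rng.uniform(0.1, 0.9, loci)
    G = rng.binomial(2, f, size=(n, loci)).astype(np.int8)
    for _ in range(gens):
        mo = rng.integers(0, n, n)
        fa = rng.integers(0, n, n)
        G = (
            (rng.random((n, loci)) < G[mo] / 2.0).astype(np.int8)
            + (rng.random((n, loci)) < G[fa] / 2.0).astype(np.int8)
        )
    return G


def _toy_pedigree(variant: str) -> PedigreeTable:
    if variant == "equal-RS":
        # 4 parents born step 0, each with exactly 2 of the 4 offspring slots
        sex = np.array([0, 0, 1, 1, 0, 1, 0, 1], dtype=np.int8)
        birth = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int32)
        mother = np.array([NO_PARENT] * 4 + [0, 0, 1, 1], dtype=np.int64)
        father = np.array([NO_PARENT] * 4 + [2, 2, 3, 3], dtype=np.int64)
    elif variant == "skewed-RS":
        # one cohort-0 parent holds all 8 offspring; fathers from outside
        sex = np.array([1, 0, 0, 1, 1] + [0] * 8, dtype=np.int8)
        birth = np.array([-1, 0, 0, 0, 0] + [1] * 8, dtype=np.int32)
        mother = np.array([NO_PARENT] * 5 + [1] * 8, dtype=np.int64)
        father = np.array([NO_PARENT] * 5 + [0] * 8, dtype=np.int64)
    else:
        raise ConfigError(f"unknown toy pedigree variant {variant!r}")
    n = len(sex)
    return PedigreeTable(
        sex=sex,
        birth_step=birth,
        deme_birth=np.zeros(n, dtype=np.int16),
        mother=mother,
        father=father,
        death_step=np.full(n, 99, dtype=np.int32),
        alive_at_end=np.zeros(n, dtype=bool),
        end_step=98,
        migrations=pd.DataFrame(columns=["id", "step", "from_deme", "to_deme"]),
    )


def make_fixtures(kind: str, params: dict | None = None, seed: int = 0):
    """Seeded oracle fixtures with true parameters in their metadata.

    kinds: ``wf-ideal`` (ideal Wright-Fisher genotypes; params n, loci,
    sample_size, gens), ``toy-pedigree`` (params variant: equal-RS |
    skewed-RS) and ``two-deme-small`` (a small two-deme simulation; params
    cohort_size, migration, n_steps)."""
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "wf-ideal":
        n = int(params.pop("n", 200))
        loci = int(params.pop("loci", 1000))
        gens = int(params.pop("gens", 30))
        sample_size = params.pop("sample_size", None)
        if params:
            raise ConfigError(f"unknown wf-ideal params {sorted(params)}")
        G = _wf_genotypes(n, loci, gens, rng)
        if sample_size is not None:
            G = G[rng.choice(n, int(sample_size), replace=False)]
        return GenotypeMatrix(
            genotypes=G,
            chrom=np.arange(loci),
            pos=np.zeros(loci),
            individuals=np.arange(G.shape[0]),
            meta={"true_ne": n, "kind": "wf-ideal", "seed": seed},
        )
    if kind == "toy-pedigree":
        return _toy_pedigree(params.get("variant", "equal-RS"))
    if kind == "two-deme-small":
        cfg = SimConfig(
            cohort_size=int(params.get("cohort_size", 100)),
            migration=float(params.get("migration", 0.05)),
            n_steps=int(params.get("n_steps", 40)),
            sampling_start=int(params.get("sampling_start", 35)),
            sampling_end=int(params.get("n_steps", 40)),
            seed=seed,
        )
        return run(cfg)
    raise ConfigError(f"unknown fixture kind {kind!r}")
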