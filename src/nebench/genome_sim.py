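"""Gene dropping, coalescent recapitation and mutation overlay.

Genetic data are produced in two phases, mirroring hybrid forward/coalescent
simulation practice:

* **Gene dropping** (:func:`drop_genomes`): each sampled haplotype is traced
  back through the recorded pedigree.  Every meiosis draws
  ``Poisson(r * L)`` crossovers at uniform positions, so a sampled haplotype
  resolves into a tiling of ancestry segments, each inherited from one
  haplotype of a step-0 founder.  The recorded transmissions are stored as
  tskit node/edge tables (one table collection per chromosome) and
  simplified down to the sample, which keeps the exact within-pedigree
  genealogy, including any coalescences that occur inside the pedigree.

* **Recapitation** (:func:`recapitate`): the founder lineages that still
  carry sampled material are completed backwards in time under the neutral
  coalescent in a single panmictic ancestral population of diploid size
  ``ancestral_ne`` (the two demes merged; pairwise coalescence rate
  ``1/(2N)`` per generation).  Linked mode runs a Hudson
  coalescent-with-recombination over the ancestral segments; unlinked mode
  draws an independent Kingman tree per locus.

* **Mutation overlay** (:func:`overlay_mutations`): infinite-sites biallelic
  mutations fall on every branch as ``Poisson(mu * span * branch length)``
  with the ancestral state known, so the unfolded SFS is available.

Forward time is recorded in steps (years) and converted to coalescent
generations with the generation length ``T``; a pedigree transmission is one
meiosis whose recorded branch length is the parent's age over ``T`` (one
generation in expectation).  Node times are birth-based and the ancestral
coalescent clock starts at the oldest founder birth.

The two linkage modes trade realism for cost: "linked" (default; chromosomes
with physical linkage, needed for linkage-correction experiments) and
"unlinked" (every locus an independent window, sufficient for the
drift-based LD estimator and the SFS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tskit

from .errors import ConfigError, PedigreeIntegrityError, ShortfallError
from .forward_sim import NO_PARENT, PedigreeTable

__all__ = [
    "GenomeSpec",
    "default_genome_spec",
    "unlinked_genome_spec",
    "Ancestry",
    "Genealogy",
    "GenotypeMatrix",
    "drop_genomes",
    "recapitate",
    "overlay_mutations",
    "simulate_genomes",
    "subset_loci",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Genome description for the coalescent/gene-dropping phase.

    ``chromosomes`` are physical lengths in bp; rates are per bp per
    meiosis/generation; ``generation_years`` converts forward time steps
    (years) to coalescent generations.  In unlinked mode each "chromosome"
    is an independent locus window.
    """

    chromosomes: tuple[float, ...]
    recombination_rate: float = 1e-8
    mutation_rate: float = 1e-8
    generation_years: float = 1.0
    mode: str = "linked"

    def __post_init__(self):
        if len(self.chromosomes) < 1 or any(c < 1 for c in self.chromosomes):
            raise ConfigError("chromosome lengths must be >= 1 bp")
        if self.recombination_rate < 0 or self.mutation_rate < 0:
            raise ConfigError("rates must be non-negative")
        if self.generation_years <= 0:
            raise ConfigError("generation_years must be positive")
        if self.mode not in ("linked", "unlinked"):
            raise ConfigError("mode must be 'linked' or 'unlinked'")


def default_genome_spec(generation_years: float) -> GenomeSpec:
    """Benchmark default: 20 chromosomes x 5e7 bp, r = mu = 1e-8 (stand-in
    values; all configurable)."""
    return GenomeSpec(
        chromosomes=(5e7,) * 20,
        recombination_rate=1e-8,
        mutation_rate=1e-8,
        generation_years=generation_years,
        mode="linked",
    )


def unlinked_genome_spec(
    n_loci: int,
    locus_length: float = 1e3,
    mutation_rate: float = 1e-8,
    generation_years: float = 1.0,
) -> GenomeSpec:
    """Spec for ``n_loci`` fully independent locus windows."""
    return GenomeSpec(
        chromosomes=(float(locus_length),) * n_loci,
        recombination_rate=0.5,  # free recombination between loci
        mutation_rate=mutation_rate,
        generation_years=generation_years,
        mode="unlinked",
    )


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Ancestry:
    """Output of gene dropping: per-chromosome pedigree-phase genealogies.

    ``tables[c]`` holds the simplified node/edge tables for chromosome ``c``
    (samples are nodes ``2i``/``2i+1`` for the i-th sampled individual).
    ``founder_label[c]`` maps each node to its original founder-haplotype
    label (``2 * founder_id + which``) or -1 for non-root nodes.  In
    unlinked mode the single entry covers all loci at unit coordinates.
    """

    spec: GenomeSpec
    mode: str
    sample_ids: np.ndarray
    sample_times: np.ndarray  # birth-based node times, generations
    tables: list[tskit.TableCollection]
    founder_label: list[np.ndarray]
    demes: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def tree_sequences(self) -> list[tskit.TreeSequence]:
        return [t.tree_sequence() for t in self.tables]

    def segments(self) -> pd.DataFrame:
        """Ancestry-segment tiling: one row per (sample haplotype, interval)
        with the founder haplotype it descends from.  Intervals are 0-based
        half-open and tile each chromosome exactly."""
        rows = []
        for c, tabs in enumerate(self.tables):
            ts = tabs.tree_sequence()
            labels = self.founder_label[c]
            for tree in ts.trees():
                left, right = tree.interval
                for u in range(2 * self.n_samples):
                    v = u
                    while tree.parent(v) != tskit.NULL:
                        v = tree.parent(v)
                    rows.append(
                        {
                            "haplotype": u,
                            "chrom": c,
                            "left": left,
                            "right": right,
                            "founder_haplotype": int(labels[v]),
                        }
                    )
        df = pd.DataFrame(rows)
        # merge contiguous intervals with identical founder
        merged = []
        for (hap, chrom), grp in df.groupby(["haplotype", "chrom"], sort=True):
            grp = grp.sort_values("left")
            cur = None
            for r in grp.itertuples():
                if (
                    cur is not None
                    and cur["right"] == r.left
                    and cur["founder_haplotype"] == r.founder_haplotype
                ):
                    cur["right"] = r.right
                else:
                    if cur is not None:
                        merged.append(cur)
                    cur = {
                        "haplotype": hap,
                        "chrom": chrom,
                        "left": r.left,
                        "right": r.right,
                        "founder_haplotype": r.founder_haplotype,
                    }
            if cur is not None:
                merged.append(cur)
        return pd.DataFrame(merged)


@dataclass
class Genealogy:
    """Completed genealogies (pedigree phase + ancestral coalescent)."""

    spec: GenomeSpec
    mode: str
    sample_ids: np.ndarray
    tree_sequences: list[tskit.TreeSequence]
    ancestral_ne: float
    demes: np.ndarray | None = None


@dataclass
class GenotypeMatrix:
    """Sampled individuals x biallelic loci, with locus metadata.

    ``genotypes`` holds derived-allele dosages 0/1/2 (ancestral state is
    known from the simulation); ``haplotypes`` the underlying phased 0/1
    matrix (2n x L).  ``chrom``/``pos`` locate each locus (0-based positions
    internally; exporters write 1-based).
    """

    genotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    individuals: np.ndarray
    haplotypes: np.ndarray | None = None
    demes: np.ndarray | None = None
    locus_names: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.locus_names is None:
            self.locus_names = np.array(
                [f"chr{c}_{int(p)}_{i}" for i, (c, p) in enumerate(zip(self.chrom, self.pos))]
            )

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Derived/alternate allele frequency per locus (missing = -1 coded
        genotypes excluded)."""
        g = self.genotypes
        valid = g >= 0
        with np.errstate(invalid="ignore"):
            return np.where(g > 0, g, 0).sum(0) / (2.0 * valid.sum(0))

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            individuals=self.individuals,
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
            demes=self.demes,
            locus_names=self.locus_names[idx],
            meta=dict(self.meta),
        )

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        hap_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return GenotypeMatrix(
            genotypes=self.genotypes[idx],
            chrom=self.chrom,
            pos=self.pos,
            individuals=self.individuals[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[hap_idx],
            demes=None if self.demes is None else self.demes[idx],
            locus_names=self.locus_names,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def _ancestor_closure(pedigree: PedigreeTable, sample_ids: np.ndarray) -> np.ndarray:
    """Ids of samples plus all their pedigree ancestors."""
    flagged = np.zeros(len(pedigree), dtype=bool)
    frontier = np.unique(sample_ids)
    flagged[frontier] = True
    while frontier.size:
        mo = pedigree.mother[frontier]
        fa = pedigree.father[frontier]
        bad = (mo == NO_PARENT) != (fa == NO_PARENT)
        if bad.any():
            raise PedigreeIntegrityError(
                f"individual {frontier[bad][0]} has exactly one recorded parent"
            )
        parents = np.unique(np.concatenate([mo, fa]))
        parents = parents[parents != NO_PARENT]
        parents = parents[~flagged[parents]]
        flagged[parents] = True
        frontier = parents
    return np.flatnonzero(flagged)


def _meiosis_breaks(rng, rate: float, length: float) -> np.ndarray:
    n = rng.poisson(rate * length)
    if n == 0:
        return np.empty(0)
    return np.sort(rng.uniform(0, length, n))


def drop_genomes(
    pedigree: PedigreeTable,
    sample_ids,
    spec: GenomeSpec,
    rng: np.random.Generator,
    demes=None,
) -> Ancestry:
    """Transmit genomes through the recorded pedigree with recombination.

    Records every relevant meiosis as tskit edges and simplifies to the
    sampled haplotypes, keeping founder haplotypes as tree roots
    (``keep_input_roots``).  Works per chromosome in linked mode; in
    unlinked mode loci are traced with free recombination (independent
    Mendelian segregation per locus) via :func:`_drop_unlinked`.
    """
    sample_ids = np.asarray(sample_ids, dtype=np.int64)
    if sample_ids.size == 0:
        raise ConfigError("at least one sample is required")
    T = spec.generation_years
    end = pedigree.end_step
    sample_times = (end - pedigree.birth_step[sample_ids]) / T

    if spec.mode == "unlinked":
        return _drop_unlinked(pedigree, sample_ids, spec, rng, demes)

    keep = _ancestor_closure(pedigree, sample_ids)
    node_of = np.full(len(pedigree), -1, dtype=np.int64)
    node_of[keep] = np.arange(keep.size)
    times = (end - pedigree.birth_step[keep]) / T
    is_founder = pedigree.is_founder[keep]

    tables_out, labels_out = [], []
    for length in spec.chromosomes:
        tables = tskit.TableCollection(sequence_length=float(length))
        tables.time_units = "generations"
        for t in times:
            tables.nodes.add_row(flags=0, time=t)
            tables.nodes.add_row(flags=0, time=t)
        edges = tables.edges
        non_founders = keep[~is_founder]
        for child in non_founders:
            cn = node_of[child]
            for which, parent in enumerate(
                (pedigree.mother[child], pedigree.father[child])
            ):
                pn = node_of[parent]
                breaks = _meiosis_breaks(rng, spec.recombination_rate, length)
                bounds = np.concatenate([[0.0], breaks, [length]])
                start = rng.integers(0, 2)
                for i in range(len(bounds) - 1):
                    edges.add_row(
                        left=bounds[i],
                        right=bounds[i + 1],
                        parent=int(2 * pn + (start + i) % 2),
                        child=int(2 * cn + which),
                    )
        samp_nodes = []
        for sid in sample_ids:
            samp_nodes.extend([int(2 * node_of[sid]), int(2 * node_of[sid] + 1)])
        flags = tables.nodes.flags
        flags[np.array(samp_nodes)] |= tskit.NODE_IS_SAMPLE
        tables.nodes.flags = flags
        tables.sort()
        node_map = tables.simplify(
            samples=samp_nodes, keep_input_roots=True, filter_sites=False
        )
        # original haplotype label for surviving founder nodes
        label = np.full(len(tables.nodes), -1, dtype=np.int64)
        founder_inds = keep[is_founder]
        for find in founder_inds:
            for which in range(2):
                old = 2 * node_of[find] + which
                new = node_map[old]
                if new != tskit.NULL:
                    label[new] = 2 * find + which
        tables_out.append(tables)
        labels_out.append(label)

    return Ancestry(
        spec=spec,
        mode="linked",
        sample_ids=sample_ids,
        sample_times=sample_times,
        tables=tables_out,
        founder_label=labels_out,
        demes=None if demes is None else np.asarray(demes),
    )


def _drop_unlinked(
    pedigree: PedigreeTable,
    sample_ids: np.ndarray,
    spec: GenomeSpec,
    rng: np.random.Generator,
    demes,
) -> Ancestry:
    """Trace every locus independently to founder haplotypes.

    Maintains an (n_haplotypes x n_loci) matrix of current ancestor
    haplotype ids and walks birth steps backwards; one Mendelian draw is
    made per (ancestor haplotype, locus), so lineages that meet in the same
    haplotype stay merged, which preserves identity-by-descent sharing
    exactly.  The per-locus genealogy is assembled as a polytomy at each
    founder haplotype (the internal pedigree merge heights are collapsed;
    see the methods note for why this is negligible for mutations).
    """
    _ = _ancestor_closure(pedigree, sample_ids)  # integrity check
    L = len(spec.chromosomes)
    n = sample_ids.size
    T = spec.generation_years
    end = pedigree.end_step
    haps = np.repeat(2 * sample_ids, 2)
    haps[1::2] += 1
    M = np.tile(haps[:, None], (1, L)).astype(np.int64)

    birth = pedigree.birth_step
    max_birth = int(birth[sample_ids].max())
    for t in range(max_birth, 0, -1):
        mask = birth[M >> 1] == t
        if not mask.any():
            continue
        vals = M[mask]
        cols = np.nonzero(mask)[1]
        uvals, uidx = np.unique(vals, return_inverse=True)
        uinds = uvals >> 1
        parent = np.where(uvals % 2 == 0, pedigree.mother[uinds], pedigree.father[uinds])
        bits = rng.integers(0, 2, size=(uvals.size, L), dtype=np.int64)
        M[mask] = 2 * parent[uidx] + bits[uidx, cols]

    sample_times = (end - birth[sample_ids]) / T
    node_time = np.repeat(sample_times, 2)
    founder_time = (end - birth) / T

    tables = tskit.TableCollection(sequence_length=float(L))
    tables.time_units = "generations"
    for t in node_time:
        tables.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=float(t))
    label_list = [-1] * (2 * n)
    for j in range(L):
        col = M[:, j]
        uf, inv = np.unique(col, return_inverse=True)
        for k, fhap in enumerate(uf):
            members = np.flatnonzero(inv == k)
            ft = float(founder_time[fhap >> 1])
            self_hit = members[haps[members] == fhap]
            if self_hit.size:
                # the founder haplotype is itself sampled: its own sample
                # node is the lineage root at this locus
                root = int(self_hit[0])
                label_list[root] = int(fhap)
                for m in members:
                    if m != root:
                        tables.edges.add_row(float(j), float(j + 1), root, int(m))
            else:
                root = tables.nodes.add_row(flags=0, time=ft)
                label_list.append(int(fhap))
                for m in members:
                    tables.edges.add_row(float(j), float(j + 1), root, int(m))
    tables.sort()
    return Ancestry(
        spec=spec,
        mode="unlinked",
        sample_ids=sample_ids,
        sample_times=sample_times,
        tables=[tables],
        founder_label=[np.array(label_list)],
        demes=None if demes is None else np.asarray(demes),
    )


# ---------------------------------------------------------------------------
# recapitation
# ---------------------------------------------------------------------------


@dataclass
class _Lineage:
    """A coalescent lineage: sorted disjoint segments of ancestral material.

    Each segment is ``[left, right, node, n_under]`` with ``n_under`` the
    number of sampled haplotypes descending from it.
    """

    segments: list  # list[list]

    @property
    def left(self):
        return self.segments[0][0]

    @property
    def right(self):
        return self.segments[-1][1]


def _merge_lineages(a: _Lineage, b: _Lineage, node_id: int, n_total: int, edges, length):
    """Coalesce two lineages into a parent node; returns surviving material."""
    out = []
    ia = ib = 0
    sa, sb = a.segments, b.segments
    while ia < len(sa) or ib < len(sb):
        if ib == len(sb) or (ia < len(sa) and sa[ia][1] <= sb[ib][0]):
            out.append(list(sa[ia])); ia += 1; continue
        if ia == len(sa) or sb[ib][1] <= sa[ia][0]:
            out.append(list(sb[ib])); ib += 1; continue
        # overlap
        l = max(sa[ia][0], sb[ib][0])
        r = min(sa[ia][1], sb[ib][1])
        if sa[ia][0] < l:
            out.append([sa[ia][0], l, sa[ia][2], sa[ia][3]])
        if sb[ib][0] < l:
            out.append([sb[ib][0], l, sb[ib][2], sb[ib][3]])
        edges.append((l, r, node_id, sa[ia][2]))
        edges.append((l, r, node_id, sb[ib][2]))
        n_under = sa[ia][3] + sb[ib][3]
        if n_under < n_total:
            out.append([l, r, node_id, n_under])
        # trim consumed parts
        if sa[ia][1] > r:
            sa[ia] = [r, sa[ia][1], sa[ia][2], sa[ia][3]]
        else:
            ia += 1
        if sb[ib][1] > r:
            sb[ib] = [r, sb[ib][1], sb[ib][2], sb[ib][3]]
        else:
            ib += 1
    out.sort(key=lambda s: s[0])
    # merge contiguous same-node same-count pieces
    merged = []
    for seg in out:
        if merged and merged[-1][2] == seg[2] and merged[-1][3] == seg[3] and merged[-1][1] == seg[0]:
            merged[-1][1] = seg[1]
        else:
            merged.append(seg)
    return merged


def _root_lineages(tables: tskit.TableCollection, n_samples: int):
    """Extract (interval, root, n_samples_under) lineages still needing
    coalescence, grouped per root node."""
    ts = tables.tree_sequence()
    per_root: dict[int, list] = {}
    for tree in ts.trees():
        left, right = tree.interval
        for root in tree.roots:
            cnt = tree.num_samples(root)
            if 0 < cnt < 2 * n_samples:
                per_root.setdefault(root, []).append([left, right, root, cnt])
    lineages = []
    for root, segs in per_root.items():
        segs.sort(key=lambda s: s[0])
        merged = []
        for s in segs:
            if merged and merged[-1][1] == s[0] and merged[-1][3] == s[3]:
                merged[-1][1] = s[1]
            else:
                merged.append(list(s))
        lineages.append(_Lineage(merged))
    return lineages


def recapitate(
    ancestry: Ancestry,
    ancestral_ne: float,
    rng: np.random.Generator,
) -> Genealogy:
    """Complete founder lineages under the neutral coalescent.

    All demes are merged into one panmictic ancestral population of diploid
    size ``ancestral_ne``; pair coalescence rate ``1/(2 * ancestral_ne)``
    per generation.  Linked mode uses a Hudson coalescent-with-recombination
    over ancestral segments; unlinked mode (free recombination between loci)
    draws one Kingman tree per locus.
    """
    if ancestral_ne <= 0:
        raise ConfigError("ancestral_ne must be positive")
    out = []
    for c, src in enumerate(ancestry.tables):
        tables = src.copy()
        if ancestry.mode == "unlinked":
            _recapitate_unlinked(tables, ancestry.n_samples, ancestral_ne, rng)
        else:
            _recapitate_hudson(
                tables,
                ancestry.n_samples,
                ancestral_ne,
                ancestry.spec.recombination_rate,
                rng,
            )
        tables.sort()
        out.append(tables.tree_sequence())
    return Genealogy(
        spec=ancestry.spec,
        mode=ancestry.mode,
        sample_ids=ancestry.sample_ids,
        tree_sequences=out,
        ancestral_ne=float(ancestral_ne),
        demes=ancestry.demes,
    )


def _recapitate_unlinked(tables, n_samples, N, rng):
    # one independent Kingman draw per unit-width locus (free recombination
    # between loci, even where adjacent loci share identical pedigree trees)
    ts = tables.tree_sequence()
    node_time = tables.nodes.time
    new_edges = []
    new_times = []
    next_node = len(tables.nodes)
    for tree in ts.trees():
        roots = [r for r in tree.roots if tree.num_samples(r) > 0]
        if len(roots) < 2:
            continue
        t0 = max(node_time[r] for r in roots)
        lo, hi = (int(round(v)) for v in tree.interval)
        for j in range(lo, hi):
            left, right = float(j), float(j + 1)
            t = t0
            active = list(roots)
            while len(active) > 1:
                k = len(active)
                t += rng.exponential(1.0 / (k * (k - 1) / 2.0 / (2.0 * N)))
                i, jj = rng.choice(k, size=2, replace=False)
                node = next_node
                next_node += 1
                new_times.append(t)
                new_edges.append((left, right, node, active[i]))
                new_edges.append((left, right, node, active[jj]))
                active = [a for idx, a in enumerate(active) if idx not in (i, jj)]
                active.append(node)
    for t in new_times:
        tables.nodes.add_row(flags=0, time=t)
    for l, r, p, ch in new_edges:
        tables.edges.add_row(l, r, int(p), int(ch))


def _recapitate_hudson(tables, n_samples, N, rec_rate, rng):
    lineages = _root_lineages(tables, n_samples)
    n_total = 2 * n_samples
    if len(lineages) < 2:
        return
    t = max(tables.nodes.time[seg[2]] for lin in lineages for seg in lin.segments)
    edges: list[tuple] = []
    node_times: list[float] = []
    next_node = len(tables.nodes)

    def add_node(time):
        nonlocal next_node
        node_times.append(time)
        next_node += 1
        return next_node - 1

    while len(lineages) > 1:
        k = len(lineages)
        extents = np.array([lin.right - lin.left for lin in lineages])
        rate_rec = rec_rate * extents.sum()
        rate_coa = k * (k - 1) / 2.0 / (2.0 * N)
        t += rng.exponential(1.0 / (rate_rec + rate_coa))
        if rng.random() < rate_rec / (rate_rec + rate_coa):
            # recombination: split one lineage at a uniform point in its extent
            li = rng.choice(k, p=extents / extents.sum())
            lin = lineages[li]
            pos = rng.uniform(lin.left, lin.right)
            left_segs, right_segs = [], []
            for seg in lin.segments:
                if seg[1] <= pos:
                    left_segs.append(seg)
                elif seg[0] >= pos:
                    right_segs.append(seg)
                else:
                    left_segs.append([seg[0], pos, seg[2], seg[3]])
                    right_segs.append([pos, seg[1], seg[2], seg[3]])
            if left_segs and right_segs:
                lineages[li] = _Lineage(left_segs)
                lineages.append(_Lineage(right_segs))
            continue
        i, j = sorted(rng.choice(k, size=2, replace=False))
        node = add_node(t)
        lj = lineages.pop(j)
        li_ = lineages.pop(i)
        surviving = _merge_lineages(li_, lj, node, n_total, edges, None)
        if surviving:
            lineages.append(_Lineage(surviving))

    # new nodes were assigned ids sequentially from len(tables.nodes)
    for time in node_times:
        tables.nodes.add_row(flags=0, time=time)
    for l, r, p, ch in edges:
        tables.edges.add_row(float(l), float(r), int(p), int(ch))


# ---------------------------------------------------------------------------
# mutation overlay and genotype extraction
# ---------------------------------------------------------------------------


def overlay_mutations(
    genealogy: Genealogy,
    rng: np.random.Generator,
    mutation_rate: float | None = None,
) -> GenotypeMatrix:
    """Drop infinite-sites mutations and extract genotypes.

    Every edge receives ``Poisson(mu * span * branch_length)`` mutations at
    uniform (continuous) positions within its interval; the ancestral state
    is 0, so unfolded spectra are available downstream.  In unlinked mode
    the per-unit rate is ``mu * locus_length`` because each locus window
    occupies one coordinate unit.
    """
    spec = genealogy.spec
    mu = spec.mutation_rate if mutation_rate is None else mutation_rate
    hap_blocks, chrom_l, pos_l = [], [], []
    for c, ts in enumerate(genealogy.tree_sequences):
        rate = mu * (spec.chromosomes[0] if genealogy.mode == "unlinked" else 1.0)
        tables = ts.dump_tables()
        times = tables.nodes.time
        e = tables.edges
        blen = times[e.parent] - times[e.child]
        span = e.right - e.left
        counts = rng.poisson(rate * blen * span)
        edge_idx = np.repeat(np.arange(len(counts)), counts)
        if edge_idx.size:
            positions = rng.uniform(e.left[edge_idx], e.right[edge_idx])
            nodes = e.child[edge_idx]
            order = np.argsort(positions, kind="stable")
            positions, nodes = positions[order], nodes[order]
            keep = np.concatenate([[True], np.diff(positions) > 0])
            positions, nodes = positions[keep], nodes[keep]
            n_mut = positions.size
            tables.sites.set_columns(
                position=positions,
                ancestral_state=np.full(n_mut, ord("0"), dtype=np.int8),
                ancestral_state_offset=np.arange(n_mut + 1, dtype=np.uint64),
            )
            tables.mutations.set_columns(
                site=np.arange(n_mut, dtype=np.int32),
                node=nodes.astype(np.int32),
                derived_state=np.full(n_mut, ord("1"), dtype=np.int8),
                derived_state_offset=np.arange(n_mut + 1, dtype=np.uint64),
                time=np.full(n_mut, tskit.UNKNOWN_TIME),
            )
        tables.sort()
        mts = tables.tree_sequence()
        if mts.num_sites:
            H = mts.genotype_matrix()  # sites x sample-haplotypes
            hap_blocks.append(H.T.astype(np.int8))
            site_pos = mts.tables.sites.position
            if genealogy.mode == "unlinked":
                chrom_l.append(np.floor(site_pos).astype(int))
                pos_l.append((site_pos % 1.0) * spec.chromosomes[0])
            else:
                chrom_l.append(np.full(mts.num_sites, c, dtype=int))
                pos_l.append(site_pos.copy())
    if hap_blocks:
        haplotypes = np.concatenate(hap_blocks, axis=1)
        chrom = np.concatenate(chrom_l)
        pos = np.concatenate(pos_l)
    else:
        haplotypes = np.zeros((2 * len(genealogy.sample_ids), 0), dtype=np.int8)
        chrom = np.zeros(0, dtype=int)
        pos = np.zeros(0)
    genotypes = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
    return GenotypeMatrix(
        genotypes=genotypes,
        chrom=chrom,
        pos=pos,
        individuals=genealogy.sample_ids.copy(),
        haplotypes=haplotypes,
        demes=None if genealogy.demes is None else genealogy.demes.copy(),
        meta={"ancestral_ne": genealogy.ancestral_ne, "mode": genealogy.mode},
    )


def simulate_genomes(
    pedigree: PedigreeTable,
    sample_ids,
    spec: GenomeSpec,
    ancestral_ne: float,
    rng: np.random.Generator,
    demes=None,
) -> GenotypeMatrix:
    """Convenience pipeline: drop -> recapitate -> mutate -> genotypes."""
    anc = drop_genomes(pedigree, sample_ids, spec, rng, demes=demes)
    gen = recapitate(anc, ancestral_ne, rng)
    return overlay_mutations(gen, rng)


def subset_loci(
    gm: GenotypeMatrix,
    n_loci: int,
    maf_min: float,
    rng: np.random.Generator,
    n_per_deme: int | None = None,
) -> GenotypeMatrix:
    """Benchmark subsetting: individuals first, then a uniform draw of loci.

    When ``n_per_deme`` is given, that many individuals are drawn uniformly
    per deme; loci are then screened for minor-allele frequency >=
    ``maf_min`` (and polymorphism) *within the retained individuals*, and
    ``n_loci`` of them drawn without replacement.  Shortfalls raise with
    counts.
    """
    out = gm
    if n_per_deme is not None:
        if out.demes is None:
            raise ConfigError("genotype matrix has no deme labels")
        keep = []
        for d in np.unique(out.demes):
            members = np.flatnonzero(out.demes == d)
            if members.size < n_per_deme:
                raise ShortfallError(
                    f"individuals in deme {d}", n_per_deme, members.size
                )
            keep.append(rng.choice(members, size=n_per_deme, replace=False))
        out = out.take_individuals(np.sort(np.concatenate(keep)))
    maf = out.maf()
    eligible = np.flatnonzero((maf >= maf_min) & (maf > 0))
    if eligible.size < n_loci:
        raise ShortfallError("loci passing the MAF screen", n_loci, eligible.size)
    chosen = np.sort(rng.choice(eligible, size=n_loci, replace=False))
    return out.take_loci(chosen)
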