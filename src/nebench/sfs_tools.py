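"""Site-frequency spectra: construction, Watterson Ne, dadi-format export.

The SFS summarises allele-frequency distributions: ``xi_i`` counts variants
whose derived allele (unfolded; ancestral states are known in simulation) or
minor allele (folded) occurs ``i`` times among ``n`` sampled haplotypes.  A
joint SFS over two demes is an ``(n1+1) x (n2+1)`` matrix of derived-count
combinations.  Model-based demographic inference on the spectrum is
delegated to external tools that consume the dadi text format written here;
the only estimator implemented is the constant-size Watterson diagnostic

    theta_W = S / a_n,   a_n = sum_{i=1}^{n-1} 1/i,   Ne = theta_W / (4 mu l)

from the total segregating-site count ``S`` and mutation target ``mu * l``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import NeEstimate
from .errors import ConfigError, FormatError, NebenchError
from .genome_sim import GenotypeMatrix

__all__ = [
    "SFS",
    "compute_sfs",
    "compute_joint_sfs",
    "fold_sfs",
    "watterson_ne",
    "export_dadi_sfs",
    "read_dadi_sfs",
]


@dataclass
class SFS:
    """Site-frequency counts for one sample of ``n`` haplotypes.

    ``counts[i]`` is ``xi_i`` for ``i = 1..n-1`` (unfolded) or
    ``i = 1..floor(n/2)`` (folded); index 0 and, when unfolded, index n are
    the monomorphic classes (kept so dadi round-trips exactly, masked on
    export)."""

    n: int
    counts: np.ndarray  # length n+1 (unfolded) or floor(n/2)+1 (folded)
    folded: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        want = (self.n // 2 + 1) if self.folded else (self.n + 1)
        if len(self.counts) != want:
            raise ConfigError(
                f"counts must have length {want} for n={self.n} "
                f"({'folded' if self.folded else 'unfolded'})"
            )
        if np.any(self.counts < 0):
            raise ConfigError("SFS counts must be non-negative")

    @property
    def segregating_sites(self) -> int:
        hi = len(self.counts) if self.folded else self.n
        return int(self.counts[1:hi].sum())

    def spectrum(self) -> np.ndarray:
        """Polymorphic classes only (xi_1 ..)."""
        hi = len(self.counts) if self.folded else self.n
        return self.counts[1:hi].copy()


def compute_sfs(data, fold: bool = False, n_haplotypes: int | None = None) -> SFS:
    """Tally the SFS of a haplotype (0/1) or genotype (0/1/2) matrix.

    Unfolded spectra require known ancestral states (allele 0), which holds
    for all simulated data here; pass ``fold=True`` for a minor-allele
    spectrum.  A :class:`GenotypeMatrix` contributes 2 haplotypes per
    individual (dosages are derived-allele counts).
    """
    if isinstance(data, GenotypeMatrix):
        counts_per_site = data.genotypes.clip(min=0).sum(axis=0)
        n = 2 * data.n_individuals
    else:
        arr = np.asarray(data)
        counts_per_site = arr.sum(axis=0)
        n = arr.shape[0] if n_haplotypes is None else n_haplotypes
        if arr.size and arr.max() > 1:
            n = 2 * arr.shape[0]  # genotype dosages
    if n < 2:
        raise NebenchError("need at least 2 haplotypes")
    xi = np.bincount(counts_per_site, minlength=n + 1)[: n + 1]
    sfs = SFS(n=n, counts=xi, folded=False)
    return fold_sfs(sfs) if fold else sfs


def compute_joint_sfs(gm: GenotypeMatrix) -> np.ndarray:
    """Joint (two-deme) SFS using deme-at-sampling labels.

    Returns an ``(n1+1) x (n2+1)`` matrix of per-site derived-count pairs,
    with ``n_d`` the haplotype count of deme ``d`` (ordered by label)."""
    if gm.demes is None:
        raise ConfigError("genotype matrix has no deme labels")
    demes = np.unique(gm.demes)
    if len(demes) != 2:
        raise ConfigError(f"joint SFS needs exactly 2 demes, found {len(demes)}")
    g = gm.genotypes.clip(min=0)
    d1 = g[gm.demes == demes[0]].sum(axis=0)
    d2 = g[gm.demes == demes[1]].sum(axis=0)
    n1 = 2 * int((gm.demes == demes[0]).sum())
    n2 = 2 * int((gm.demes == demes[1]).sum())
    joint = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    np.add.at(joint, (d1, d2), 1)
    return joint


def fold_sfs(sfs: SFS) -> SFS:
    """Fold to the minor-allele spectrum: ``xi'_i = xi_i + xi_{n-i}``
    (classes ``i`` and ``n-i`` pooled; the central class not doubled)."""
    if sfs.folded:
        return sfs
    n = sfs.n
    half = n // 2
    folded = np.zeros(half + 1, dtype=np.int64)
    for i in range(half + 1):
        j = n - i
        if j == i:
            folded[i] = sfs.counts[i]
        else:
            folded[i] = sfs.counts[i] + sfs.counts[j]
    return SFS(n=n, counts=folded, folded=True)


def watterson_ne(sfs: SFS, mu: float, seq_length: float) -> NeEstimate:
    """Watterson's constant-size Ne from the segregating-site count."""
    if mu * seq_length <= 0:
        raise ConfigError("mutation target mu * seq_length must be positive")
    if sfs.n < 2:
        raise NebenchError("need n >= 2")
    a_n = (1.0 / np.arange(1, sfs.n)).sum()
    s = sfs.segregating_sites
    theta = s / a_n
    point = theta / (4.0 * mu * seq_length)
    aux = {"theta_w": theta, "segregating_sites": s, "a_n": a_n}
    if s == 0:
        return NeEstimate(point=0.0, method="sfs", aux=aux)
    return NeEstimate(point=point, method="sfs", aux=aux)


# ---------------------------------------------------------------------------
# dadi SFS text format
# ---------------------------------------------------------------------------


def export_dadi_sfs(sfs: SFS | np.ndarray, path) -> None:
    """Write the dadi/moments SFS text format.

    Line 1: dimension sizes plus ``folded``/``unfolded``; line 2: the
    frequency array flattened row-major; line 3: the mask (1 = masked; the
    monomorphic corner classes).  Joint spectra are passed as the
    ``(n1+1) x (n2+1)`` matrix from :func:`compute_joint_sfs`.
    """
    if isinstance(sfs, SFS):
        counts = sfs.counts
        dims = [len(counts)]
        header_flag = "folded" if sfs.folded else "unfolded"
        mask = np.zeros(len(counts), dtype=int)
        mask[0] = 1
        if not sfs.folded:
            mask[-1] = 1
    else:
        arr = np.asarray(sfs)
        if arr.ndim != 2:
            raise ConfigError("joint SFS must be a 2-D matrix")
        counts = arr.ravel()
        dims = list(arr.shape)
        header_flag = "unfolded"
        mask = np.zeros(arr.shape, dtype=int)
        mask[0, 0] = 1
        mask[-1, -1] = 1
        mask = mask.ravel()
    with open(path, "w") as fh:
        fh.write(" ".join(str(d) for d in dims) + f" {header_flag}\n")
        fh.write(" ".join(str(int(c)) for c in counts) + "\n")
        fh.write(" ".join(str(int(m)) for m in mask) + "\n")


def read_dadi_sfs(path):
    """Read the format written by :func:`export_dadi_sfs`.

    Returns an :class:`SFS` for one dimension or the raw matrix for two.
    """
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip()]
    if len(lines) < 2:
        raise FormatError("dadi SFS file needs a header and a counts line")
    head = lines[0].split()
    flag = "unfolded"
    if head and head[-1] in ("folded", "unfolded"):
        flag = head[-1]
        head = head[:-1]
    try:
        dims = [int(h) for h in head]
    except ValueError as exc:
        raise FormatError(f"bad dimension header: {lines[0]!r}", 1) from exc
    counts = np.array([int(float(v)) for v in lines[1].split()], dtype=np.int64)
    if counts.size != int(np.prod(dims)):
        raise FormatError("counts do not match header dimensions", 2)
    if len(dims) == 1:
        if flag == "folded":
            # folded file of n haplotypes has floor(n/2)+1 entries; recover n
            # is ambiguous (n or n+1); store with even n convention
            n = 2 * (dims[0] - 1)
            return SFS(n=n, counts=counts, folded=True)
        return SFS(n=dims[0] - 1, counts=counts, folded=False)
    return counts.reshape(dims)
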