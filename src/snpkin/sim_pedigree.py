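"""Gene-dropping pedigree simulation with exact IBD truth.

Founder genotypes are drawn under Hardy-Weinberg equilibrium from a
configurable B-allele-frequency spectrum; each meiosis recombines the
parental haplotypes with crossovers placed by a Poisson process at the
map rate (Haldane model, no interference).  Founder haplotypes carry
unique labels, so the true per-marker IBD state of any pair — and hence
the realized Cotterman coefficients — is known exactly.  Genotyping
noise (symmetric adjacent-genotype errors, no-calls) and forced runs of
homozygosity can be layered on top.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import NC, GenotypeTable

# GRCh37-scale autosome lengths in Mb
_HUMAN_AUTOSOME_MB = [
    249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135, 134,
    115, 107, 103, 90, 81, 78, 59, 63, 48, 51,
]


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths, marker density, map rate, and frequency spectrum."""

    chromosomes: tuple[tuple[str, int], ...]   # (name, length_bp)
    marker_counts: tuple[int, ...]             # markers per chromosome
    cm_per_mb: float = 1.0
    freq_low: float = 0.05                     # uniform B-allele frequency bounds
    freq_high: float = 0.95

    def __post_init__(self):
        if len(self.chromosomes) != len(self.marker_counts):
            raise ValueError("marker_counts must align with chromosomes")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if not (0.0 < self.freq_low <= self.freq_high < 1.0):
            raise ValueError("frequency bounds must satisfy 0 < low <= high < 1")

    @property
    def n_markers(self) -> int:
        return sum(self.marker_counts)

    @classmethod
    def from_scaled_human(
        cls, n_markers: int, scale: float, cm_per_mb: float = 1.0
    ) -> "GenomeModel":
        lengths = [int(mb * scale * 1_000_000) for mb in _HUMAN_AUTOSOME_MB]
        total = sum(lengths)
        counts = [max(2, round(n_markers * l / total)) for l in lengths]
        return cls(
            chromosomes=tuple((str(i + 1), l) for i, l in enumerate(lengths)),
            marker_counts=tuple(counts),
            cm_per_mb=cm_per_mb,
        )

    @classmethod
    def desk_scale(cls, n_markers: int = 50_000) -> "GenomeModel":
        """22 autosomes at ~10% human length; fast enough for test suites."""
        return cls.from_scaled_human(n_markers, scale=0.10)

    @classmethod
    def full_scale(cls, n_markers: int = 872_242) -> "GenomeModel":
        """Full human autosome lengths at SNP-array marker density."""
        return cls.from_scaled_human(n_markers, scale=1.0)


@dataclass(frozen=True)
class NoiseModel:
    """Genotyping noise: error/no-call rates and forced-homozygous intervals.

    ``roh`` entries are (sample, chromosome, start_bp, end_bp) intervals
    within which the sample is made homozygous (second haplotype copied
    from the first) before genotypes are formed.
    """

    error_rate: float = 0.01
    no_call_rate: float = 0.005
    roh: tuple[tuple[str, str, int, int], ...] = ()

    def __post_init__(self):
        for r in (self.error_rate, self.no_call_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0, 1)")


class PedigreeSpec:
    """Individuals with optional (father, mother) links; founders have none."""

    def __init__(self, parents: dict[str, tuple[str, str] | None]):
        self.parents = dict(parents)
        for name, p in self.parents.items():
            if p is not None:
                f, m = p
                if f not in self.parents or m not in self.parents:
                    raise ValueError(f"{name}: parent not in pedigree")
        self.order = self._toposort()

    def _toposort(self) -> list[str]:
        order, done = [], set()

        def visit(name, stack):
            if name in done:
                return
            if name in stack:
                raise ValueError(f"pedigree cycle involving {name!r}")
            p = self.parents[name]
            if p is not None:
                visit(p[0], stack | {name})
                visit(p[1], stack | {name})
            done.add(name)
            order.append(name)

        for name in self.parents:
            visit(name, set())
        return order

    @property
    def founders(self) -> list[str]:
        return [n for n in self.order if self.parents[n] is None]


@dataclass
class SimTruth:
    """Founder-haplotype labels per sample: exact IBD bookkeeping."""

    markers: pd.DataFrame
    labels: dict[str, tuple[np.ndarray, np.ndarray]]

    def ibd_states(self, sample_a: str, sample_b: str) -> np.ndarray:
        """Per-marker true IBD state (0/1/2) for a pair."""
        a1, a2 = self.labels[sample_a]
        b1, b2 = self.labels[sample_b]
        m11, m12 = a1 == b1, a1 == b2
        m21, m22 = a2 == b1, a2 == b2
        ibd2 = (m11 & m22) | (m12 & m21)
        ibd1 = ~ibd2 & (m11 | m12 | m21 | m22)
        return (2 * ibd2 + ibd1).astype(np.int8)

    def realized_k(self, sample_a: str, sample_b: str) -> tuple[float, float, float]:
        return realized_k(
            self.ibd_states(sample_a, sample_b),
            self.markers["chromosome"].to_numpy(),
            self.markers["position"].to_numpy(),
        )


def realized_k(
    true_ibd: np.ndarray, chromosomes: np.ndarray, positions: np.ndarray
) -> tuple[float, float, float]:
    """Base-pair-length-weighted fractions of IBD0/1/2 along the genome.

    Each marker is weighted by its Voronoi cell between neighbouring
    markers on the same chromosome (chromosome span = first to last
    marker), so contiguous same-state runs contribute their segment
    length.
    """
    weights = np.zeros(len(positions), dtype=float)
    for chrom in dict.fromkeys(chromosomes):
        idx = np.flatnonzero(chromosomes == chrom)
        pos = positions[idx].astype(float)
        if len(pos) == 1:
            continue
        w = np.empty(len(pos))
        w[0] = (pos[1] - pos[0]) / 2.0
        w[-1] = (pos[-1] - pos[-2]) / 2.0
        if len(pos) > 2:
            w[1:-1] = (pos[2:] - pos[:-2]) / 2.0
        weights[idx] = w
    total = weights.sum()
    ks = [float(weights[true_ibd == s].sum() / total) for s in (0, 1, 2)]
    return (ks[0], ks[1], ks[2])


# ---------------------------------------------------------------------------
# Gene dropping

def _draw_markers(genome: GenomeModel, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for (name, length), count in zip(genome.chromosomes, genome.marker_counts):
        pos = np.sort(rng.choice(np.int64(length), size=count, replace=False)) + 1
        for p in pos:
            rows.append((name, int(p)))
    df = pd.DataFrame(rows, columns=["chromosome", "position"])
    df.insert(0, "marker_id", [f"snp{i}" for i in range(len(df))])
    return df


def _meiosis(
    hap_pair: tuple[np.ndarray, np.ndarray],
    label_pair: tuple[np.ndarray, np.ndarray],
    genome: GenomeModel,
    chrom_slices: list[slice],
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: Haldane crossovers per chromosome, random start phase.

    Alleles and founder-haplotype labels are transmitted through the same
    crossover realization so the truth track matches the genotypes.
    """
    h0, h1 = hap_pair
    l0, l1 = label_pair
    gamete = np.empty_like(h0)
    glabel = np.empty_like(l0)
    for (name, length), sl in zip(genome.chromosomes, chrom_slices):
        morgans = (length / 1e6) * genome.cm_per_mb / 100.0
        n_cross = rng.poisson(morgans)
        cross = np.sort(rng.uniform(0, length, size=n_cross))
        # parity of crossovers passed, plus a random starting haplotype
        parity = np.searchsorted(cross, positions[sl]) % 2
        start = rng.integers(2)
        take = (parity + start) % 2
        gamete[sl] = np.where(take == 0, h0[sl], h1[sl])
        glabel[sl] = np.where(take == 0, l0[sl], l1[sl])
    return gamete, glabel


def simulate_cohort(
    genome: GenomeModel,
    pedigree: PedigreeSpec,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeTable, SimTruth]:
    """Gene-drop a pedigree: genotypes for every individual plus IBD truth.

    Deterministic for a fixed seed.  Noise is applied independently per
    sample after transmission, so truth tracks refer to the error-free
    transmitted haplotypes.
    """
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    markers = _draw_markers(genome, rng)
    n = len(markers)
    freqs = rng.uniform(genome.freq_low, genome.freq_high, size=n)
    positions = markers["position"].to_numpy()
    chrom_slices = []
    start = 0
    for (name, _), _count in zip(genome.chromosomes, genome.marker_counts):
        count = int((markers["chromosome"] == name).sum())
        chrom_slices.append(slice(start, start + count))
        start += count

    haplos: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    labels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    next_label = 0
    for name in pedigree.order:
        p = pedigree.parents[name]
        if p is None:
            h = tuple(
                (rng.random(n) < freqs).astype(np.int8) for _ in range(2)
            )
            lab = (
                np.full(n, next_label, dtype=np.int32),
                np.full(n, next_label + 1, dtype=np.int32),
            )
            next_label += 2
        else:
            father, mother = p
            h_pat, l_pat = _meiosis(
                haplos[father], labels[father], genome, chrom_slices, positions, rng
            )
            h_mat, l_mat = _meiosis(
                haplos[mother], labels[mother], genome, chrom_slices, positions, rng
            )
            h, lab = (h_pat, h_mat), (l_pat, l_mat)
        haplos[name] = h
        labels[name] = lab

    samples = list(pedigree.order)
    calls = np.empty((n, len(samples)), dtype=np.int8)
    chroms = markers["chromosome"].to_numpy()
    for j, s in enumerate(samples):
        h0, h1 = (arr.copy() for arr in haplos[s])
        for rs, rchrom, rstart, rend in noise.roh:
            if rs == s:
                mask = (chroms == rchrom) & (positions >= rstart) & (positions <= rend)
                h1[mask] = h0[mask]
        calls[:, j] = _apply_noise(h0 + h1, noise, rng)

    table = GenotypeTable(markers, samples, calls)
    return table, SimTruth(markers=markers.copy(), labels=labels)


def _apply_noise(geno: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Adjacent-genotype error flips (AA<->AB<->BB) then no-calls."""
    g = geno.astype(np.int8).copy()
    n = len(g)
    if noise.error_rate > 0:
        err = rng.random(n) < noise.error_rate
        direction = rng.integers(2, size=n)  # AB errs to AA or BB equally
        g[err & (g == 0)] = 1
        g[err & (g == 2)] = 1
        het_err = err & (geno == 1)
        g[het_err] = np.where(direction[het_err] == 0, 0, 2)
    if noise.no_call_rate > 0:
        g[rng.random(n) < noise.no_call_rate] = NC
    return g


# ---------------------------------------------------------------------------
# Built-in relationship scenarios

SCENARIOS = (
    "identical", "parent_child", "full_sib", "half_sib",
    "avuncular", "first_cousin", "r_1_64", "unrelated",
)

# pedigree-expected (k0, k1, k2) for each scenario
EXPECTED_K: dict[str, tuple[float, float, float]] = {
    "identical": (0.0, 0.0, 1.0),
    "parent_child": (0.0, 1.0, 0.0),
    "full_sib": (0.25, 0.5, 0.25),
    "half_sib": (0.5, 0.5, 0.0),
    "avuncular": (0.5, 0.5, 0.0),
    "first_cousin": (0.75, 0.25, 0.0),
    "r_1_64": (1.0 - 0.03125, 0.03125, 0.0),
    "unrelated": (1.0, 0.0, 0.0),
}


def _scenario_pedigree(name: str) -> tuple[PedigreeSpec, tuple[str, str]]:
    F = None
    if name == "parent_child":
        ped = {"F": F, "M": F, "C": ("F", "M")}
        return PedigreeSpec(ped), ("F", "C")
    if name == "full_sib":
        ped = {"F": F, "M": F, "C1": ("F", "M"), "C2": ("F", "M")}
        return PedigreeSpec(ped), ("C1", "C2")
    if name == "half_sib":
        ped = {"F": F, "M1": F, "M2": F, "C1": ("F", "M1"), "C2": ("F", "M2")}
        return PedigreeSpec(ped), ("C1", "C2")
    if name == "avuncular":
        ped = {
            "GF": F, "GM": F, "A": ("GF", "GM"), "B": ("GF", "GM"),
            "S": F, "C": ("B", "S"),
        }
        return PedigreeSpec(ped), ("A", "C")
    if name == "first_cousin":
        ped = {
            "GF": F, "GM": F, "A": ("GF", "GM"), "B": ("GF", "GM"),
            "S1": F, "S2": F, "C1": ("A", "S1"), "C2": ("B", "S2"),
        }
        return PedigreeSpec(ped), ("C1", "C2")
    if name == "r_1_64":
        # descendants 2 and 3 meioses below a founding sib pair:
        # kinship (1/4) * (1/2)^5 = 1/128, r = 1/64, k1 = 1/32
        ped = {
            "GF": F, "GM": F, "A": ("GF", "GM"), "B": ("GF", "GM"),
            "S1": F, "S2": F, "S3": F, "S4": F, "S5": F,
            "D1": ("A", "S1"), "D2": ("D1", "S2"),
            "E1": ("B", "S3"), "E2": ("E1", "S4"), "E3": ("E2", "S5"),
        }
        return PedigreeSpec(ped), ("D2", "E3")
    if name == "unrelated":
        ped = {"U1": F, "U2": F}
        return PedigreeSpec(ped), ("U1", "U2")
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


@dataclass
class SimulatedPair:
    """Two genotype vectors with their exact IBD truth."""

    scenario: str
    table: GenotypeTable                 # restricted to the two samples
    sample_a: str
    sample_b: str
    true_ibd: np.ndarray                 # per-marker state in {0, 1, 2}
    realized_k: tuple[float, float, float]
    expected_k: tuple[float, float, float]


def scenario(
    name: str,
    genome: GenomeModel | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> SimulatedPair:
    """Gene-drop the minimal pedigree realizing a named relationship."""
    genome = genome or GenomeModel.desk_scale()
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if name == "identical":
        # one individual; the genotype vector is duplicated, then noise is
        # applied independently to each copy (technical-replicate model)
        ped = PedigreeSpec({"U1": None})
        clean = NoiseModel(error_rate=0.0, no_call_rate=0.0)
        table, truth = simulate_cohort(genome, ped, clean, rng)
        geno = table.calls[:, 0]
        calls = np.column_stack(
            [_apply_noise(geno, noise, rng), _apply_noise(geno, noise, rng)]
        )
        pair_table = GenotypeTable(table.markers, ["U1_a", "U1_b"], calls)
        true_ibd = np.full(table.n_markers, 2, dtype=np.int8)
        return SimulatedPair(
            scenario=name, table=pair_table, sample_a="U1_a", sample_b="U1_b",
            true_ibd=true_ibd, realized_k=(0.0, 0.0, 1.0),
            expected_k=EXPECTED_K[name],
        )

    ped, (a, b) = _scenario_pedigree(name)
    table, truth = simulate_cohort(genome, ped, noise, rng)
    pair_table = table.subset_samples([a, b])
    true_ibd = truth.ibd_states(a, b)
    return SimulatedPair(
        scenario=name, table=pair_table, sample_a=a, sample_b=b,
        true_ibd=true_ibd, realized_k=truth.realized_k(a, b),
        expected_k=EXPECTED_K[name],
    )


# ---------------------------------------------------------------------------
# Truth writers

def write_truth(pair: SimulatedPair, bed_path, json_path, seed=None) -> None:
    """BED-like truth segments (0-based half-open) plus a realized_k summary."""
    chroms = pair.table.markers["chromosome"].to_numpy()
    pos = pair.table.markers["position"].to_numpy()
    with open(bed_path, "w") as fh:
        fh.write(f"# scenario={pair.scenario} seed={seed}\n")
        fh.write("chrom\tstart\tend\tibd_state\n")
        for chrom in dict.fromkeys(chroms):
            idx = np.flatnonzero(chroms == chrom)
            st = pair.true_ibd[idx]
            p = pos[idx]
            run_start = 0
            for i in range(1, len(idx) + 1):
                if i == len(idx) or st[i] != st[run_start]:
                    fh.write(
                        f"{chrom}\t{p[run_start] - 1}\t{p[i - 1]}\t{int(st[run_start])}\n"
                    )
                    run_start = i
    with open(json_path, "w") as fh:
        json.dump(
            {
                "scenario": pair.scenario,
                "sample_a": pair.sample_a,
                "sample_b": pair.sample_b,
                "seed": seed,
                "realized_k": list(pair.realized_k),
                "expected_k": list(pair.expected_k),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
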