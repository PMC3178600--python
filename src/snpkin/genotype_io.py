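"""Genotype matrix and marker-map input/output.

Genotypes are stored in unphased AB coding relative to the two alleles
observed at each marker: ``AA``/``AB``/``BB`` plus ``NC`` for a failed
call.  Heterozygotes are unordered, so ``BA`` is normalised to ``AB`` on
input.  Internally calls are an int8 matrix with codes ``0/1/2`` for the
B-allele dosage and ``-1`` for no-calls.

Supported formats: PLINK text PED/MAP and TPED/TFAM, and a simple TSV
matrix (rows = markers, columns = samples).  All readers are transparent
to gzip (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

# int8 call codes: B-allele dosage, -1 = no-call
AA, AB, BB, NC = 0, 1, 2, -1

CALL_TO_CODE = {"AA": AA, "AB": AB, "BA": AB, "BB": BB, "NC": NC}
CODE_TO_CALL = {AA: "AA", AB: "AB", BB: "BB", NC: "NC"}


class GenotypeFormatError(ValueError):
    """Malformed genotype input (ragged rows, bad tokens, >2 alleles)."""


def normalize_chromosome(label: object) -> str:
    """Canonical chromosome name: strips ``chr``, maps 23/24/25 and M to X/Y/MT."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    up = s.upper()
    if up in {"23", "X"}:
        return "X"
    if up in {"24", "Y"}:
        return "Y"
    if up in {"25", "MT", "M"}:
        return "MT"
    return s


def is_autosome(chromosome: str) -> bool:
    c = normalize_chromosome(chromosome)
    return c.isdigit() and 1 <= int(c) <= 22


def chromosome_sort_key(chromosome: str):
    c = normalize_chromosome(chromosome)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25}
    if c in special:
        return (1, special[c], "")
    return (2, 0, c)


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP on the marker map (1-based bp position)."""

    marker_id: str
    chromosome: str
    position: int

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"marker {self.marker_id}: position must be >= 1")


@dataclass
class GenotypeTable:
    """Markers plus per-sample call vectors.

    ``markers`` is a DataFrame with columns ``marker_id``, ``chromosome``,
    ``position`` sorted by (chromosome, position); ``calls`` has shape
    (n_markers, n_samples) aligned to ``markers`` and ``samples``.
    """

    markers: pd.DataFrame
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.markers["marker_id"].duplicated().any():
            dups = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"]
            raise ValueError(f"duplicate marker ids: {list(dups[:5])}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample)]

    def sorted_by_position(self) -> "GenotypeTable":
        keys = [chromosome_sort_key(c) for c in self.markers["chromosome"]]
        order = pd.DataFrame(
            {"k": keys, "pos": self.markers["position"].to_numpy()}
        ).sort_values(["k", "pos"], kind="stable").index.to_numpy()
        markers = self.markers.iloc[order].reset_index(drop=True)
        return GenotypeTable(markers, list(self.samples), self.calls[order])

    def filter_autosomes(self) -> "GenotypeTable":
        """Drop X/Y/MT (and other non-autosomal) markers; samples unchanged."""
        keep = self.markers["chromosome"].map(is_autosome).to_numpy()
        if not keep.any():
            warnings.warn("no autosomal markers remain after filtering")
        markers = self.markers.loc[keep].reset_index(drop=True)
        return GenotypeTable(markers, list(self.samples), self.calls[keep])

    def subset_samples(self, samples: list[str]) -> "GenotypeTable":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeTable(self.markers.copy(), list(samples), self.calls[:, idx])

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.markers["chromosome"]:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# TSV matrix format: columns marker_id, chromosome, position, <sample ids...>

def read_matrix(tsv_path) -> GenotypeTable:
    """Read the TSV matrix format (cells in AA/AB/BA/BB/NC)."""
    with _open_text(tsv_path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    if df.shape[1] < 4:
        raise GenotypeFormatError(
            f"{tsv_path}: expected marker_id, chromosome, position plus >=1 sample column"
        )
    samples = list(df.columns[3:])
    markers = pd.DataFrame(
        {
            "marker_id": df.iloc[:, 0].astype(str),
            "chromosome": df.iloc[:, 1].map(normalize_chromosome),
            "position": df.iloc[:, 2].astype(int),
        }
    )
    calls = np.empty((len(df), len(samples)), dtype=np.int8)
    for j, s in enumerate(samples):
        col = df[s].str.strip().str.upper()
        bad = ~col.isin(CALL_TO_CODE)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise GenotypeFormatError(
                f"{tsv_path}: invalid call {col.iloc[i]!r} at marker "
                f"{markers['marker_id'].iloc[i]!r}, sample {s!r}"
            )
        calls[:, j] = col.map(CALL_TO_CODE).to_numpy(dtype=np.int8)
    return GenotypeTable(markers, samples, calls).sorted_by_position()


def write_matrix(table: GenotypeTable, tsv_path) -> None:
    df = table.markers.copy()
    for j, s in enumerate(table.samples):
        df[s] = [CODE_TO_CALL[int(c)] for c in table.calls[:, j]]
    df.to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK text formats

def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with _open_text(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise GenotypeFormatError(
                    f"{map_path}:{ln}: expected 4 columns (chrom, id, cM, bp), got {len(parts)}"
                )
            rows.append(
                (normalize_chromosome(parts[0]), parts[1], int(parts[3]))
            )
    return pd.DataFrame(rows, columns=["chromosome", "marker_id", "position"])


def _recode_allele_pairs(a1: np.ndarray, a2: np.ndarray, marker_ids) -> np.ndarray:
    """Recode per-marker allele pairs (strings, '0' = missing) to AB dosage codes.

    The A allele is the lexicographically smaller of the two observed
    alleles; IBS statistics are invariant to this arbitrary assignment.
    """
    n_markers, n_samples = a1.shape
    calls = np.full((n_markers, n_samples), NC, dtype=np.int8)
    bad_markers = []
    for i in range(n_markers):
        x1, x2 = a1[i], a2[i]
        missing = (x1 == "0") | (x2 == "0")
        alleles = sorted(set(x1[~missing]) | set(x2[~missing]))
        if len(alleles) > 2:
            bad_markers.append(str(marker_ids[i]))
            continue
        if not alleles:
            continue  # all missing: stays NC
        if len(alleles) == 1:
            # monomorphic: the single observed allele is the A allele
            dosage = np.zeros(n_samples, dtype=np.int8)
        else:
            b = alleles[1]  # B = lexicographically larger observed allele
            dosage = (x1 == b).astype(np.int8) + (x2 == b).astype(np.int8)
        dosage[missing] = NC
        calls[i] = dosage
    if bad_markers:
        raise GenotypeFormatError(
            f"markers with more than 2 alleles: {', '.join(bad_markers[:10])}"
            + ("..." if len(bad_markers) > 10 else "")
        )
    return calls


def read_plink(ped_path, map_path) -> GenotypeTable:
    """Read PLINK text PED/MAP into a GenotypeTable."""
    markers = _read_map(map_path)
    n_markers = len(markers)
    samples: list[str] = []
    rows_a1, rows_a2 = [], []
    with _open_text(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise GenotypeFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_markers} fields "
                    f"(6 metadata + 2 alleles x {n_markers} markers), got {len(parts)}"
                )
            samples.append(parts[1])
            geno = np.array(parts[6:], dtype=object)
            rows_a1.append(geno[0::2])
            rows_a2.append(geno[1::2])
    if not samples:
        raise GenotypeFormatError(f"{ped_path}: no samples")
    a1 = np.stack(rows_a1).T  # (markers, samples)
    a2 = np.stack(rows_a2).T
    calls = _recode_allele_pairs(a1, a2, markers["marker_id"].to_numpy())
    return GenotypeTable(markers, samples, calls).sorted_by_position()


def read_tped(tped_path, tfam_path) -> GenotypeTable:
    """Read PLINK transposed text TPED/TFAM into a GenotypeTable."""
    samples = []
    with _open_text(tfam_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GenotypeFormatError(f"{tfam_path}:{ln}: expected >=2 columns")
            samples.append(parts[1])
    n = len(samples)
    marker_rows, rows_a1, rows_a2 = [], [], []
    with _open_text(tped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4 + 2 * n:
                raise GenotypeFormatError(
                    f"{tped_path}:{ln}: expected {4 + 2 * n} fields, got {len(parts)}"
                )
            marker_rows.append(
                (normalize_chromosome(parts[0]), parts[1], int(parts[3]))
            )
            geno = np.array(parts[4:], dtype=object)
            rows_a1.append(geno[0::2])
            rows_a2.append(geno[1::2])
    markers = pd.DataFrame(marker_rows, columns=["chromosome", "marker_id", "position"])
    a1 = np.stack(rows_a1)
    a2 = np.stack(rows_a2)
    calls = _recode_allele_pairs(a1, a2, markers["marker_id"].to_numpy())
    return GenotypeTable(markers, samples, calls).sorted_by_position()


def write_plink(table: GenotypeTable, ped_path, map_path) -> None:
    """Write PED/MAP with literal A/B alleles ('0 0' for no-calls)."""
    with open(map_path, "w") as fh:
        for row in table.markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position}\n")
    pair = {AA: "A A", AB: "A B", BB: "B B", NC: "0 0"}
    with open(ped_path, "w") as fh:
        for j, s in enumerate(table.samples):
            geno = " ".join(pair[int(c)] for c in table.calls[:, j])
            fh.write(f"FAM {s} 0 0 0 -9 {geno}\n")


# ---------------------------------------------------------------------------
# Sample sheet

def read_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV sample sheet with columns ``sample_id`` and ``group``."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise GenotypeFormatError(f"{path}: sample sheet must have a {col!r} column")
    if df["sample_id"].duplicated().any():
        raise GenotypeFormatError(f"{path}: duplicate sample ids in sheet")
    return df
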