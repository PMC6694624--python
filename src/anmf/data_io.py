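"""Reading, writing and validating drug-disease association data.

The model consumes three matrices:

* ``R`` — an ``m x n`` binary association matrix (1 = drug verified to treat
  disease),
* ``DrugSim`` — an ``m x m`` drug-drug similarity matrix with values in
  ``[0, 1]`` (e.g. Tanimoto scores over chemical fingerprints),
* ``DiseaseSim`` — an ``n x n`` disease-disease similarity matrix in
  ``[0, 1]`` (e.g. text-mining similarity of disease descriptions).

All files are tab-separated with a header row and first-column labels.  The
association file may alternatively be a 2- or 3-column edge list
``drug_id <TAB> disease_id [<TAB> value]``; the format is auto-detected from
the column count, and edge-list identifiers are resolved against the
similarity-matrix labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "DatasetStats",
    "DataError",
    "load_dataset",
    "save_dataset",
    "dataset_stats",
    "drug_profile",
    "disease_profile",
]

_SYM_TOL = 1e-8


class DataError(ValueError):
    """Raised for malformed or inconsistent input matrices."""


@dataclass
class Dataset:
    """An in-memory drug-disease dataset.

    Attributes
    ----------
    drug_ids, disease_ids
        Unique string identifiers for the rows/columns of ``R``.
    R
        ``m x n`` float array with entries exactly 0.0 or 1.0.
    drug_sim, disease_sim
        Symmetric similarity matrices with unit diagonal, values in [0, 1].
    """

    drug_ids: list[str]
    disease_ids: list[str]
    R: np.ndarray
    drug_sim: np.ndarray
    disease_sim: np.ndarray

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def validate(self) -> "Dataset":
        """Check invariants in place; symmetrize similarities if needed."""
        m, n = len(self.drug_ids), len(self.disease_ids)
        if len(set(self.drug_ids)) != m:
            raise DataError("duplicate drug identifiers")
        if len(set(self.disease_ids)) != n:
            raise DataError("duplicate disease identifiers")
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (m, n):
            raise DataError(f"association matrix shape {self.R.shape} != ({m}, {n})")
        bad = ~np.isin(self.R, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"non-binary association value {self.R[i, j]!r} at "
                f"({self.drug_ids[i]}, {self.disease_ids[j]})"
            )
        self.drug_sim = self._check_sim(self.drug_sim, m, "DrugSim")
        self.disease_sim = self._check_sim(self.disease_sim, n, "DiseaseSim")
        return self

    @staticmethod
    def _check_sim(S: np.ndarray, size: int, name: str) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        if S.shape != (size, size):
            raise DataError(f"{name} shape {S.shape} != ({size}, {size})")
        if np.nanmin(S) < -_SYM_TOL or np.nanmax(S) > 1 + _SYM_TOL:
            raise DataError(f"{name} has values outside [0, 1]")
        if not np.allclose(S, S.T, atol=_SYM_TOL):
            warnings.warn(f"{name} is asymmetric; symmetrizing as (S + S.T)/2")
            S = (S + S.T) / 2.0
        return S


@dataclass
class DatasetStats:
    """Summary counts and sparsity of an association matrix."""

    n_drugs: int
    n_diseases: int
    n_interactions: int
    sparsity: float


def dataset_stats(d: Dataset) -> DatasetStats:
    """Counts and interaction density (interactions / (drugs x diseases))."""
    m, n = d.n_drugs, d.n_diseases
    k = int(d.R.sum())
    return DatasetStats(m, n, k, k / (m * n))


def drug_profile(d: Dataset, i: int) -> np.ndarray:
    """Row ``i`` of R: the interaction profile of drug ``i`` (copy)."""
    if not 0 <= i < d.n_drugs:
        raise IndexError(f"drug index {i} out of range [0, {d.n_drugs})")
    return d.R[i].copy()


def disease_profile(d: Dataset, j: int) -> np.ndarray:
    """Column ``j`` of R: the interaction profile of disease ``j`` (copy)."""
    if not 0 <= j < d.n_diseases:
        raise IndexError(f"disease index {j} out of range [0, {d.n_diseases})")
    return d.R[:, j].copy()


def _read_labeled_matrix(path: str | Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.empty and df.shape[1] == 0:
        raise DataError(f"{name} file {path} is empty")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df


def load_dataset(
    assoc_path: str | Path,
    drug_sim_path: str | Path,
    disease_sim_path: str | Path,
) -> Dataset:
    """Load and validate a dataset from TSV files.

    The association file may be a dense labeled matrix or an edge list; the
    similarity files must be dense labeled matrices.  Drug/disease order is
    taken from the similarity files; association entries absent from an edge
    list are zero.
    """
    for p in (assoc_path, drug_sim_path, disease_sim_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")

    dsim = _read_labeled_matrix(drug_sim_path, "DrugSim")
    if list(dsim.index) != list(dsim.columns):
        raise DataError("DrugSim row and column labels differ")
    zsim = _read_labeled_matrix(disease_sim_path, "DiseaseSim")
    if list(zsim.index) != list(zsim.columns):
        raise DataError("DiseaseSim row and column labels differ")
    drug_ids = list(dsim.index)
    disease_ids = list(zsim.index)

    with open(assoc_path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    # dense matrices carry a header row (empty corner cell, disease-id columns);
    # edge lists have <= 3 columns and start with a drug id
    is_dense = (first[0] == ""
                or len(first) > 4
                or (len(first) == len(disease_ids) + 1
                    and set(first[1:]) == set(disease_ids)))
    if not is_dense:
        R = _read_edge_list(assoc_path, drug_ids, disease_ids)
    else:
        adf = _read_labeled_matrix(assoc_path, "association")
        missing = set(adf.index) - set(drug_ids)
        if missing:
            raise DataError(f"drug id {sorted(missing)[0]!r} not present in DrugSim labels")
        missing = set(adf.columns) - set(disease_ids)
        if missing:
            raise DataError(f"disease id {sorted(missing)[0]!r} not present in DiseaseSim labels")
        if set(adf.index) != set(drug_ids) or set(adf.columns) != set(disease_ids):
            raise DataError("association matrix labels do not cover the similarity labels")
        R = adf.loc[drug_ids, disease_ids].to_numpy(dtype=float)

    ds = Dataset(drug_ids, disease_ids, R, dsim.to_numpy(dtype=float), zsim.to_numpy(dtype=float))
    return ds.validate()


def _read_edge_list(path: str | Path, drug_ids: list[str], disease_ids: list[str]) -> np.ndarray:
    edges = pd.read_csv(path, sep="\t", header=None, dtype=str)
    drug_pos = {d: i for i, d in enumerate(drug_ids)}
    dis_pos = {z: j for j, z in enumerate(disease_ids)}
    R = np.zeros((len(drug_ids), len(disease_ids)))
    for row in edges.itertuples(index=False):
        drug, disease = str(row[0]), str(row[1])
        value = float(row[2]) if len(row) > 2 and not pd.isna(row[2]) else 1.0
        if drug not in drug_pos:
            raise DataError(f"drug id {drug!r} not present in DrugSim labels")
        if disease not in dis_pos:
            raise DataError(f"disease id {disease!r} not present in DiseaseSim labels")
        if value not in (0.0, 1.0):
            raise DataError(f"non-binary association value {value!r} for ({drug}, {disease})")
        R[drug_pos[drug], dis_pos[disease]] = value
    return R


def save_dataset(d: Dataset, assoc_path: str | Path, drug_sim_path: str | Path,
                 disease_sim_path: str | Path) -> None:
    """Write the three matrices as dense labeled TSVs (full float precision)."""
    pd.DataFrame(d.R, index=d.drug_ids, columns=d.disease_ids).to_csv(
        assoc_path, sep="\t", float_format=lambda v: repr(float(v)))
    pd.DataFrame(d.drug_sim, index=d.drug_ids, columns=d.drug_ids).to_csv(
        drug_sim_path, sep="\t", float_format=lambda v: repr(float(v)))
    pd.DataFrame(d.disease_sim, index=d.disease_ids, columns=d.disease_ids).to_csv(
        disease_sim_path, sep="\t", float_format=lambda v: repr(float(v)))
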