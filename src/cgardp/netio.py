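"""Heterogeneous drug-disease network I/O and validation.

The network universe consists of three labeled matrices: a drug-drug
similarity matrix ``R`` (values in [0, 1], unit diagonal, symmetric), a
disease-disease similarity matrix ``D`` with the same properties, and a
binary drug-disease association matrix ``A``.  All three are stored on disk
as UTF-8 tab-separated files with a header row of column identifiers and a
first column of row identifiers.

Drug similarity can alternatively be derived from binary chemical
substructure fingerprints (869 PubChem-style bits per drug) via cosine
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-6
_INVARIANT_TOL = 1e-8
DEFAULT_FINGERPRINT_BITS = 869


@dataclass
class HeteroNetwork:
    """Drug/disease similarity matrices plus binary associations.

    Attributes
    ----------
    drug_ids, disease_ids:
        Ordered unique node labels; their lengths fix ``n_drugs``/``n_diseases``.
    R, D:
        Symmetric similarity matrices in [0, 1] with unit diagonal.
    A:
        Binary association matrix of shape (n_drugs, n_diseases).
    """

    drug_ids: list[str]
    disease_ids: list[str]
    R: np.ndarray
    D: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = [str(i) for i in self.drug_ids]
        self.disease_ids = [str(i) for i in self.disease_ids]
        self.R = np.asarray(self.R, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.validate()

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def validate(self) -> None:
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise KeyError("duplicate drug ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise KeyError("duplicate disease ids")
        nr, nd = self.n_drugs, self.n_diseases
        if self.R.shape != (nr, nr):
            raise ValueError(f"R shape {self.R.shape} != ({nr}, {nr})")
        if self.D.shape != (nd, nd):
            raise ValueError(f"D shape {self.D.shape} != ({nd}, {nd})")
        if self.A.shape != (nr, nd):
            raise ValueError(f"A shape {self.A.shape} != ({nr}, {nd})")
        for name, m in (("R", self.R), ("D", self.D)):
            if not np.allclose(m, m.T, atol=_INVARIANT_TOL):
                raise ValueError(f"{name} is not symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=_INVARIANT_TOL):
                raise ValueError(f"{name} diagonal is not 1")
            if m.min() < -_INVARIANT_TOL or m.max() > 1 + _INVARIANT_TOL:
                raise ValueError(f"{name} has entries outside [0, 1]")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("A has entries outside {0, 1}")

    def copy_with_associations(self, A: np.ndarray) -> "HeteroNetwork":
        """A view of the same universe with a replaced association matrix."""
        return HeteroNetwork(self.drug_ids, self.disease_ids, self.R, self.D, A)


@dataclass
class FingerprintMatrix:
    """Binary chemical substructure fingerprints, one row per drug."""

    drug_ids: list[str]
    bits: np.ndarray
    n_bits: int = field(default=DEFAULT_FINGERPRINT_BITS)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=float)
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise KeyError("duplicate drug ids")
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.drug_ids):
            raise ValueError("fingerprint rows must match drug ids")
        if self.bits.shape[1] != self.n_bits:
            raise ValueError(
                f"expected {self.n_bits} fingerprint bits, got {self.bits.shape[1]}"
            )
        if not np.isin(self.bits, (0.0, 1.0)).all():
            raise ValueError("fingerprints must be binary")


def _read_labeled_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _symmetrize(name: str, m: np.ndarray) -> np.ndarray:
    asym = np.abs(m - m.T).max() if m.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(
            f"{name} asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}; "
            "refusing to symmetrize (input likely corrupt)"
        )
    return (m + m.T) / 2.0


def load_network(
    r_path: str | Path, d_path: str | Path, a_path: str | Path
) -> HeteroNetwork:
    """Load and validate R, D, A from labeled TSV files.

    Mild asymmetry (<= 1e-6) in R or D is silently repaired by averaging
    with the transpose; anything larger raises.
    """
    r_df, d_df, a_df = map(_read_labeled_tsv, (r_path, d_path, a_path))
    for name, df in (("R", r_df), ("D", d_df), ("A", a_df)):
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise KeyError(f"duplicate ids in {name}")
    if list(r_df.index) != list(r_df.columns):
        raise ValueError("R row ids differ from column ids")
    if list(d_df.index) != list(d_df.columns):
        raise ValueError("D row ids differ from column ids")
    if list(a_df.index) != list(r_df.index):
        raise ValueError("A row ids differ from drug ids in R")
    if list(a_df.columns) != list(d_df.index):
        raise ValueError("A column ids differ from disease ids in D")
    R = _symmetrize("R", r_df.to_numpy(dtype=float))
    D = _symmetrize("D", d_df.to_numpy(dtype=float))
    return HeteroNetwork(
        list(r_df.index), list(d_df.index), R, D, a_df.to_numpy(dtype=float)
    )


def write_network(net: HeteroNetwork, out_dir: str | Path) -> dict[str, Path]:
    """Write R.tsv, D.tsv, A.tsv under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    frames = {
        "R": pd.DataFrame(net.R, index=net.drug_ids, columns=net.drug_ids),
        "D": pd.DataFrame(net.D, index=net.disease_ids, columns=net.disease_ids),
        "A": pd.DataFrame(net.A, index=net.drug_ids, columns=net.disease_ids),
    }
    for name, df in frames.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", float_format="%.17g")
        paths[name] = p
    return paths


def cosine_drug_similarity(fp: FingerprintMatrix) -> np.ndarray:
    """Pairwise cosine similarity of fingerprint rows.

    All-zero rows (no recorded substructures) get similarity 0 to every
    other drug and 1 to themselves, so the output still satisfies the
    similarity-matrix invariants.
    """
    bits = fp.bits
    norms = np.linalg.norm(bits, axis=1)
    if not norms.any():
        raise ValueError("all fingerprint rows are zero")
    safe = np.where(norms > 0, norms, 1.0)
    sim = (bits @ bits.T) / np.outer(safe, safe)
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim
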