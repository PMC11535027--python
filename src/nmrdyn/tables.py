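"""Tabular I/O, probe identities, and bond-vector extraction from structures.

Probes are identified by (residue_number, atom_label[, stereo]).  Residue
numbering is taken verbatim from the input tables (mature-protein numbering,
e.g. PDZ 349-458); no renumbering is ever applied.

All tables are UTF-8 CSV/TSV with a mandatory header row.  A declared column
schema maps file headers onto canonical field names; a documented default
schema ships with the package (see DEFAULT_SCHEMA).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeID",
    "BondVector",
    "SchemaError",
    "TableIntegrityError",
    "DEFAULT_SCHEMA",
    "ATOM_LABELS",
    "read_probe_table",
    "write_results",
    "extract_bond_vectors",
]

#: closed vocabulary of probe atom labels
ATOM_LABELS = frozenset(
    {
        "N-H",
        "Ile-d1",
        "Leu-d1",
        "Leu-d2",
        "Val-g1",
        "Val-g2",
        "Met-e",
        "Ala-b",
        "Thr-g2",
    }
)

#: default column mapping file header -> canonical name
DEFAULT_SCHEMA: Mapping[str, str] = {
    "residue": "residue_number",
    "residue_type": "residue_type",
    "atom": "atom_label",
    "stereo": "stereo",
}


class SchemaError(ValueError):
    """A declared column is missing from the file."""


class TableIntegrityError(ValueError):
    """Duplicate probe keys or unparseable numeric rows."""


@dataclass(frozen=True, order=True)
class ProbeID:
    """Identity of an NMR probe: a backbone amide or a methyl group.

    ``atom_label`` is drawn from the closed vocabulary :data:`ATOM_LABELS`;
    stereo-specific methyls carry an optional ``proR``/``proS`` tag (a package
    convention — peak lists rarely standardise this).
    """

    residue_number: int
    atom_label: str = "N-H"
    residue_type: str = ""
    stereo: str | None = None

    def __post_init__(self):
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if self.atom_label not in ATOM_LABELS:
            raise ValueError(
                f"atom_label {self.atom_label!r} not in the closed vocabulary "
                f"{sorted(ATOM_LABELS)}"
            )
        if self.stereo not in (None, "proR", "proS"):
            raise ValueError(f"stereo must be None, 'proR' or 'proS', got {self.stereo!r}")

    @property
    def key(self) -> tuple:
        return (self.residue_number, self.atom_label, self.stereo)

    def __str__(self) -> str:  # e.g. "I150:Ile-d1"
        tag = f"/{self.stereo}" if self.stereo else ""
        return f"{self.residue_type}{self.residue_number}:{self.atom_label}{tag}"


@dataclass(frozen=True)
class BondVector:
    """Unit vector of a relaxation-active bond, tied to a structure model."""

    probe: ProbeID
    unit_vector: tuple[float, float, float]
    source: str = ""

    def __post_init__(self):
        n = math.sqrt(sum(c * c for c in self.unit_vector))
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"unit_vector norm {n} deviates from 1 by more than 1e-6")


def _resolve_schema(columns: Sequence[str], schema: Mapping[str, str]) -> dict:
    mapping = {}
    for file_col, canon in schema.items():
        if file_col in columns:
            mapping[file_col] = canon
    return mapping


def read_probe_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    required: Sequence[str] = ("probe|residue",),
    numeric: Sequence[str] = (),
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited probe table, validating schema and numeric fields.

    Parameters
    ----------
    path : file path (CSV or TSV; delimiter sniffed unless ``sep`` given)
    schema : column mapping applied after reading (file header -> canonical)
    required : file columns that must be present
    numeric : columns that must parse as numbers; rows failing to parse are
        rejected with a :class:`TableIntegrityError` naming their line numbers
        (1-based, counting the header as line 1)

    Duplicate (residue, atom, stereo) keys raise :class:`TableIntegrityError`.
    An empty file with a valid header returns an empty frame without error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in required:
        # "a|b" means: at least one of the alternatives must be present
        if not any(alt in df.columns for alt in col.split("|")):
            raise SchemaError(f"required column {col!r} missing from {path.name}")
    for col in numeric:
        if col not in df.columns:
            raise SchemaError(f"required numeric column {col!r} missing from {path.name}")
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & (df[col] != "")]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad)  # +2: header + 1-based
            raise TableIntegrityError(
                f"non-numeric value(s) in column {col!r} of {path.name} at line(s) {lines}"
            )
        df[col] = parsed
    if schema:
        df = df.rename(columns=_resolve_schema(df.columns, schema))
    key_cols = [c for c in ("probe", "residue", "residue_number") if c in df.columns]
    if key_cols:
        key = [key_cols[0]] + [c for c in ("atom", "atom_label", "stereo") if c in df.columns]
        extra = [
            c
            for c in ("condition", "experiment", "delay_s", "nu_cpmg_Hz", "field_T", "nucleus", "T_s", "time_s")
            if c in df.columns
        ]
        dup = df.duplicated(subset=key + extra, keep=False)
        if dup.any():
            rows = ", ".join(str(i + 2) for i in df.index[dup])
            raise TableIntegrityError(f"duplicate probe key(s) in {path.name} at line(s) {rows}")
    return df


def write_results(df: pd.DataFrame, path: str | Path, sep: str = ",") -> Path:
    """Write a results table; full float precision so read/write round-trips."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# bond vectors from PDB structures
# ---------------------------------------------------------------------------

_METHYL_PAIRS = {
    # atom_label -> (parent carbon, methyl carbon); the symmetry axis is the
    # parent->methyl carbon vector
    "Ile-d1": ("CG1", "CD1"),
    "Leu-d1": ("CG", "CD1"),
    "Leu-d2": ("CG", "CD2"),
    "Val-g1": ("CB", "CG1"),
    "Val-g2": ("CB", "CG2"),
    "Met-e": ("SD", "CE"),
    "Ala-b": ("CA", "CB"),
    "Thr-g2": ("CB", "CG2"),
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


class GeometryError(ValueError):
    """Zero-length or otherwise degenerate bond geometry."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-8:
        raise GeometryError("zero-length bond vector")
    return v / n


def _reconstruct_amide_h(res, prev_res) -> np.ndarray | None:
    """Place the amide H 1.02 A from N, opposed to the CA/C(i-1) bisector.

    X-ray structures usually lack amide protons; ideal peptide-plane geometry
    puts H in the N-CA-C(i-1) plane, opposite the bisector of those bonds.
    """
    try:
        n = res["N"].get_coord()
        ca = res["CA"].get_coord()
        c_prev = prev_res["C"].get_coord()
    except KeyError:
        return None
    u1 = _unit(ca - n)
    u2 = _unit(c_prev - n)
    direction = -_unit(u1 + u2)
    return n + 1.02 * direction


def extract_bond_vectors(
    structure_path: str | Path,
    pair_spec: str = "N-H",
    model_index: int = 0,
    chain_id: str | None = None,
    reconstruct_h: bool = True,
) -> tuple[list[BondVector], list[tuple[int, str]]]:
    """Extract unit bond vectors for relaxation analysis from a PDB file.

    ``pair_spec`` is either ``"N-H"`` (backbone amide; missing protons are
    reconstructed from ideal peptide geometry unless ``reconstruct_h=False``)
    or a methyl label such as ``"Ile-d1"`` (symmetry axis = parent->methyl
    carbon vector).

    Returns ``(vectors, skipped)`` where ``skipped`` lists
    ``(residue_number, reason)`` for residues lacking the required atoms.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    structure_path = Path(structure_path)
    if not structure_path.exists():
        raise FileNotFoundError(structure_path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure("s", str(structure_path))
        except Exception as exc:  # pragma: no cover - biopython raises various
            raise ValueError(f"unreadable structure file {structure_path.name}: {exc}") from exc
    models = list(structure)
    if not models:
        raise ValueError(f"no models in {structure_path.name}")
    model = models[model_index]
    source = f"{structure_path.stem}#model{model_index}"

    vectors: list[BondVector] = []
    skipped: list[tuple[int, str]] = []
    for chain in model:
        if chain_id is not None and chain.id != chain_id:
            continue
        residues = [r for r in chain if r.id[0] == " "]
        for i, res in enumerate(residues):
            resnum = res.id[1]
            resname = _THREE_TO_ONE.get(res.get_resname(), "X")
            if pair_spec == "N-H":
                if "N" not in res:
                    skipped.append((resnum, "missing N"))
                    continue
                n_coord = res["N"].get_coord()
                h_atom = next((a for a in ("H", "HN", "H1") if a in res), None)
                if h_atom is not None:
                    h_coord = res[h_atom].get_coord()
                elif reconstruct_h and i > 0:
                    h = _reconstruct_amide_h(res, residues[i - 1])
                    if h is None:
                        skipped.append((resnum, "cannot reconstruct H"))
                        continue
                    h_coord = h
                else:
                    skipped.append((resnum, "missing H"))
                    continue
                vec = _unit(np.asarray(h_coord, float) - np.asarray(n_coord, float))
                probe = ProbeID(resnum, "N-H", resname)
            else:
                if pair_spec not in _METHYL_PAIRS:
                    raise ValueError(f"unknown pair_spec {pair_spec!r}")
                want = {"Ile": "ILE", "Leu": "LEU", "Val": "VAL",
                        "Met": "MET", "Ala": "ALA", "Thr": "THR"}[pair_spec.split("-")[0]]
                if res.get_resname() != want:
                    continue
                parent, methyl = _METHYL_PAIRS[pair_spec]
                if parent not in res or methyl not in res:
                    skipped.append((resnum, f"missing {parent} or {methyl}"))
                    continue
                vec = _unit(
                    np.asarray(res[methyl].get_coord(), float)
                    - np.asarray(res[parent].get_coord(), float)
                )
                probe = ProbeID(resnum, pair_spec, resname)
            vectors.append(BondVector(probe, tuple(float(c) for c in vec), source))
    return vectors, skipped
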