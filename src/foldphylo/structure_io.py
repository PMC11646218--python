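"""Reading, validating and filtering Cα traces from PDB/mmCIF files.

Only the alpha-carbon trace of one polymer chain is kept: the downstream
superposition and distance metrics operate on Cα coordinates alone.  Parsing
is delegated to gemmi; this module fixes the selection policy (model 1,
altloc by occupancy, HETATM excluded) and the resolution filter applied when
assembling a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Structure",
    "StructureFormatError",
    "ChainNotFoundError",
    "EmptyTraceError",
    "read_structure",
    "write_pdb",
    "filter_resolution",
    "read_manifest",
]

# Plausible consecutive Calpha-Calpha distance range (Å); larger gaps are
# recorded as chain breaks, smaller ones indicate a corrupt trace.
CA_CA_MIN = 2.5
CA_CA_MAX = 4.5


class StructureFormatError(ValueError):
    """File could not be parsed as PDB or mmCIF."""


class ChainNotFoundError(KeyError):
    """Requested chain is absent from the file."""


class EmptyTraceError(ValueError):
    """Selected chain contains no Cα atoms."""


@dataclass
class Structure:
    """An ordered Cα trace with identifying metadata.

    Attributes
    ----------
    id : str
        Short label, conventionally PDB code plus chain (e.g. ``"1BPB_A"``).
    residues : list of (int, str)
        ``(residue_number, one_letter_code)`` per kept residue, in trace
        order; non-standard residues carry ``'X'``.
    coords : (n, 3) ndarray
        Cα coordinates in Å, same order as ``residues``.
    resolution : float or None
        Crystallographic resolution in Å; ``None`` for entries without one
        (NMR, predicted models).
    chain_breaks : set of int
        Indices ``i`` such that the gap between residue ``i`` and ``i+1``
        exceeds a plausible Cα–Cα distance.
    source_taxon : str or None
        Free-text organism annotation.
    """

    id: str
    residues: list[tuple[int, str]]
    coords: np.ndarray
    resolution: float | None = None
    source_taxon: str | None = None
    chain_breaks: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.residues) != len(self.coords):
            raise ValueError("residues and coords length mismatch")
        if self.n < 1:
            raise EmptyTraceError(f"{self.id}: empty Cα trace")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.id}: non-finite Cα coordinate")
        nums = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"{self.id}: residue numbers not strictly increasing")

    @property
    def n(self) -> int:
        return len(self.residues)

    def validate_geometry(self) -> None:
        """Check consecutive Cα–Cα distances; record large gaps as breaks."""
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        for i, dist in enumerate(d):
            if dist > CA_CA_MAX:
                self.chain_breaks.add(i)
            elif dist < CA_CA_MIN and i not in self.chain_breaks:
                raise ValueError(
                    f"{self.id}: Cα–Cα distance {dist:.2f} Å at index {i} "
                    f"below {CA_CA_MIN} Å"
                )


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved toward altloc 'A' (then lexical)
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "A"))[0]


def _chain_ca_trace(chain: gemmi.Chain) -> tuple[list[tuple[int, str]], list[list[float]]]:
    residues: list[tuple[int, str]] = []
    coords: list[list[float]] = []
    for res in chain:
        if res.is_water():
            continue
        het = res.het_flag == "H"
        cas = [a for a in res if a.name == "CA" and a.element.name == "C"]
        if not cas:
            continue
        if het and not res.is_amino_acid():
            # heteroatom entities that are not modified amino acids (ligands)
            continue
        atom = _pick_altloc(cas)
        aa = gemmi.find_tabulated_residue(res.name)
        one = aa.one_letter_code.upper() if aa and aa.is_amino_acid() else "x"
        if not one.isalpha() or one == " ":
            one = "X"
        residues.append((res.seqid.num, one if one != "x" else "X"))
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return residues, coords


def _auto_chain(model: gemmi.Model) -> gemmi.Chain:
    """First chain with ≥ 20 Cα atoms, else the first chain with any Cα."""
    fallback = None
    for chain in model:
        res, _ = _chain_ca_trace(chain)
        if len(res) >= 20:
            return chain
        if res and fallback is None:
            fallback = chain
    if fallback is None:
        raise EmptyTraceError("no chain with Cα atoms in model 1")
    return fallback


def read_structure(path: str | Path, chain: str = "auto", id: str | None = None) -> Structure:
    """Read the Cα trace of one chain from a PDB or mmCIF file.

    Model 1 only is used for multi-model (NMR) entries; altlocs resolve to
    the highest-occupancy conformer ('A' on ties); waters and non-polymer
    HETATM records are excluded.  Resolution is taken from the header when
    present.

    Parameters
    ----------
    path : str or Path
        PDB or mmCIF file (format detected from content/extension).
    chain : str
        Chain identifier, or ``"auto"`` for the first chain with at least 20
        Cα atoms (falling back to the first chain with any Cα).
    id : str, optional
        Label for the structure; defaults to ``<stem>_<chain>``.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")
    st.setup_entities()
    model = st[0]

    if chain == "auto":
        gchain = _auto_chain(model)
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise ChainNotFoundError(f"{path}: chain {chain!r} not found")
    residues, coords = _chain_ca_trace(gchain)
    if not residues:
        raise EmptyTraceError(f"{path}: chain {gchain.name!r} has no Cα atoms")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    label = id or f"{path.stem}_{gchain.name}"
    out = Structure(
        id=label,
        residues=residues,
        coords=np.asarray(coords, dtype=float),
        resolution=resolution,
    )
    out.validate_geometry()
    return out


def write_pdb(structure: Structure, path: str | Path, chain_id: str = "A") -> None:
    """Write a Cα-only PDB file (one ATOM record per residue)."""
    three = {"X": "UNK", "G": "GLY", "A": "ALA"}
    lines = []
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS."
        )
    for i, ((num, aa), xyz) in enumerate(zip(structure.residues, structure.coords), 1):
        resname = three.get(aa, "UNK") if aa in three else _one_to_three(aa)
        lines.append(
            f"ATOM  {i:5d}  CA  {resname:<3s} {chain_id}{num:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def _one_to_three(aa: str) -> str:
    return _THREE.get(aa.upper(), "UNK")


def filter_resolution(structures: Iterable[Structure], max_res: float = 4.0) -> list[Structure]:
    """Drop structures with resolution strictly above ``max_res`` Å.

    Entries without a recorded resolution (e.g. NMR structures) are kept:
    the filter targets poorly resolved crystal structures only.  Input order
    is preserved and the operation is idempotent.
    """
    return [s for s in structures if s.resolution is None or s.resolution <= max_res]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest TSV.

    Required columns: ``id``, ``path``; optional: ``chain`` (default
    ``auto``), ``clade``, ``taxon_domain``.  Relative paths resolve against
    the manifest's own directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"id", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    if "chain" not in df.columns:
        df["chain"] = "auto"
    df["chain"] = df["chain"].fillna("auto")
    df["path"] = [
        str((path.parent / p)) if not Path(p).is_absolute() else p for p in df["path"]
    ]
    return df


def load_manifest_structures(path: str | Path, max_res: float | None = 4.0) -> list[Structure]:
    """Read every structure listed in a manifest, applying the resolution filter."""
    df = read_manifest(path)
    structures = []
    for row in df.itertuples(index=False):
        structures.append(read_structure(row.path, chain=row.chain, id=row.id))
    if max_res is not None:
        structures = filter_resolution(structures, max_res=max_res)
    return structures
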