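"""PDB ingestion, fragment extraction and result writers.

Structures arrive as PDB files (single- or multi-MODEL); parsing is done
with gemmi.  Each MODEL of each file becomes one CoordinateSet holding the
selected atoms (CA, backbone N/CA/C/O, or a custom name list) ordered by
chain, residue number (with insertion code) and the selection's canonical
atom-name order.  Hetero residues and waters are excluded; for altLoc
duplicates the highest-occupancy conformer wins (ties: first in file).
Residues that do not present the full selection are skipped and reported
through `warnings`.

Internal structure indices are 0-based; residue identifiers keep the
PDB's own (1-based, possibly gapped) numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .cluster import LevelResult
from .geometry import AtomSelection, CoordinateSet
from .search import Ensemble, PairHit, SearchStats

__all__ = [
    "FragmentSpec",
    "read_models",
    "read_structures",
    "extract_fragments",
    "write_ensemble_pdb",
    "write_pairs_tsv",
    "write_stats_tsv",
    "write_clusters_tsv",
    "write_level_summary_tsv",
    "write_filter_tsv",
]

#: Maximum CA-CA distance (Å) for two residues to count as consecutive.
DEFAULT_MAX_CA_GAP = 4.5


@dataclass(frozen=True)
class FragmentSpec:
    """How to cut contiguous fragments out of chains."""

    length: int = 5
    selection: AtomSelection = AtomSelection("CA")
    max_ca_gap: float = DEFAULT_MAX_CA_GAP

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("fragment length must be >= 2")


def _residue_id(res: gemmi.Residue) -> int | str:
    icode = res.seqid.icode.strip()
    return res.seqid.num if not icode else f"{res.seqid.num}{icode}"


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> gemmi.Atom | None:
    """Highest-occupancy conformer; occupancy ties broken by file order."""
    best = None
    for atom in atoms:
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def _parse_model(
    model: gemmi.Model,
    selection: AtomSelection,
    name: str,
) -> tuple[list[tuple], np.ndarray, list[str]]:
    """Selected atoms of one MODEL in canonical order, plus skip reports."""
    wanted = selection.atom_names
    atoms: list[tuple] = []
    coords: list[list[float]] = []
    skipped: list[str] = []
    for chain in model:
        for res in chain:
            if res.het_flag != "A" or res.is_water():
                continue
            found = {}
            for aname in wanted:
                atom = _pick_altloc(a for a in res if a.name == aname)
                if atom is not None:
                    found[aname] = atom
            if len(found) < len(wanted):
                missing = [a for a in wanted if a not in found]
                skipped.append(
                    f"{name} {chain.name}/{res.name} {_residue_id(res)} "
                    f"missing {','.join(missing)}"
                )
                continue
            rid = _residue_id(res)
            for aname in wanted:
                atom = found[aname]
                atoms.append((chain.name, rid, aname))
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return atoms, np.asarray(coords, dtype=np.float64).reshape(-1, 3), skipped


def read_models(
    paths: Sequence[str | Path],
    selection: AtomSelection = AtomSelection("CA"),
) -> list[CoordinateSet]:
    """One CoordinateSet per MODEL per file (models may differ in length).

    Residues missing part of the selection are skipped with a warning;
    a file yielding no atoms at all is an error.
    """
    out: list[CoordinateSet] = []
    for path in paths:
        path = Path(path)
        try:
            structure = gemmi.read_pdb(str(path))
        except (RuntimeError, OSError) as exc:
            raise IOError(f"cannot read PDB file {path}: {exc}") from exc
        structure.setup_entities()
        multi = len(structure) > 1
        for model in structure:
            label = f"{path.stem}#{model.num}" if multi else path.stem
            atoms, coords, skipped = _parse_model(model, selection, label)
            if skipped:
                warnings.warn(
                    f"{label}: skipped {len(skipped)} residue(s) lacking the full "
                    f"selection: {'; '.join(skipped[:5])}"
                    + ("; ..." if len(skipped) > 5 else "")
                )
            if coords.shape[0] == 0:
                raise ValueError(f"no selected atoms in {label} ({path})")
            out.append(CoordinateSet(label, atoms, coords))
    if not out:
        raise ValueError("no structures read")
    return out


def read_structures(
    paths: Sequence[str | Path],
    selection: AtomSelection = AtomSelection("CA"),
) -> Ensemble:
    """Read PDB files into an Ensemble (all models must align atom-for-atom)."""
    return Ensemble(read_models(paths, selection), selection)


def extract_fragments(
    models: Sequence[CoordinateSet],
    spec: FragmentSpec = FragmentSpec(),
) -> Ensemble:
    """All contiguous `length`-residue fragments of every chain.

    A window is contiguous when residue numbers are consecutive integers
    and successive CA atoms are within ``max_ca_gap`` Å.  Windows crossing
    numbering gaps, insertion codes, or chain breaks are skipped; chains
    shorter than the window contribute nothing.  Fragment names encode
    source model, chain and starting residue.
    """
    wanted = spec.selection.atom_names
    fragments: list[CoordinateSet] = []
    for cs in models:
        # Group rows by (chain, residue) preserving order.
        per_res: dict[tuple, dict[str, int]] = {}
        res_order: list[tuple] = []
        for k, (chain, rid, aname) in enumerate(cs.atoms):
            key = (chain, rid)
            if key not in per_res:
                per_res[key] = {}
                res_order.append(key)
            per_res[key][aname] = k

        # Per chain, residues usable for fragments (full selection present).
        by_chain: dict[str, list[tuple]] = {}
        for key in res_order:
            if all(a in per_res[key] for a in wanted):
                by_chain.setdefault(key[0], []).append(key)

        for chain, residues in by_chain.items():
            for start in range(len(residues) - spec.length + 1):
                window = residues[start : start + spec.length]
                ok = True
                for (c1, r1), (c2, r2) in zip(window, window[1:]):
                    if not (
                        isinstance(r1, int)
                        and isinstance(r2, int)
                        and r2 == r1 + 1
                    ):
                        ok = False
                        break
                    if "CA" in per_res[(c1, r1)] and "CA" in per_res[(c2, r2)]:
                        d = np.linalg.norm(
                            cs.coords[per_res[(c1, r1)]["CA"]]
                            - cs.coords[per_res[(c2, r2)]["CA"]]
                        )
                        if d > spec.max_ca_gap:
                            ok = False
                            break
                if not ok:
                    continue
                rows = [per_res[key][a] for key in window for a in wanted]
                atoms = [cs.atoms[r] for r in rows]
                fragments.append(
                    CoordinateSet(
                        f"{cs.name}/{chain}:{window[0][1]}",
                        atoms,
                        cs.coords[rows],
                    )
                )
    if not fragments:
        raise ValueError("no fragments extracted")
    # Fragment atom labels differ between fragments; re-label positionally
    # so ensemble members align atom-for-atom.
    n = spec.length * len(wanted)
    relabelled = [
        CoordinateSet(
            f.name,
            [("A", 1 + k // len(wanted), wanted[k % len(wanted)]) for k in range(n)],
            f.coords,
        )
        for f in fragments
    ]
    return Ensemble(relabelled, spec.selection)


def write_ensemble_pdb(
    members: Sequence[CoordinateSet], path: str | Path
) -> None:
    """Write structures as a multi-MODEL PDB (one MODEL per member)."""
    with open(path, "w") as fh:
        for num, cs in enumerate(members, start=1):
            fh.write(f"MODEL     {num:4d}\n")
            serial = 1
            for (chain, rid, aname), (x, y, z) in zip(cs.atoms, cs.coords):
                if isinstance(rid, str):
                    num_part = int("".join(ch for ch in rid if ch.isdigit() or ch == "-"))
                    icode = rid[len(str(num_part)):] or " "
                else:
                    num_part, icode = rid, " "
                name_field = f" {aname:<3s}" if len(aname) < 4 else aname
                fh.write(
                    f"ATOM  {serial:5d} {name_field} ALA {chain[:1]}{num_part:4d}{icode[:1]}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_pairs_tsv(
    hits: Sequence[PairHit], names: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("name_i\tname_j\trmsd\n")
        for i, j, r in hits:
            fh.write(f"{names[i]}\t{names[j]}\t{r:.4f}\n")


def write_stats_tsv(stats: SearchStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("reference\tn_cmp\tretired\tstop_rmsd\n")
        for rec in stats.per_iteration:
            fh.write(f"{rec.reference}\t{rec.n_cmp}\t{rec.retired}\t{rec.stop_rmsd:.4f}\n")
        fh.write("# n_structures\tn_cmp\tall_vs_all\tratio\n")
        fh.write(stats.summary_line() + "\n")


def write_clusters_tsv(
    levels: Sequence[LevelResult], names: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("level\tthreshold\trepresentative\tmember\trmsd\n")
        for lvl, result in enumerate(levels, start=1):
            for c in result.clusters:
                for m, r in c.members:
                    fh.write(
                        f"{lvl}\t{result.threshold:g}\t{names[c.representative]}"
                        f"\t{names[m]}\t{r:.4f}\n"
                    )


def write_level_summary_tsv(
    levels: Sequence[LevelResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tn_input\tn_cmp\tall_vs_all\tratio\tn_representatives\n")
        for result in levels:
            s = result.stats
            fh.write(
                f"{result.threshold:g}\t{result.n_input}\t{s.n_cmp}\t{s.all_vs_all}"
                f"\t{s.ratio:.4f}\t{result.n_representatives}\n"
            )


def write_filter_tsv(
    removed: Sequence[tuple[int, int, float]],
    names: Sequence[str],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("removed\tkept_as\trmsd100\n")
        for rm, kept, r in removed:
            fh.write(f"{names[rm]}\t{names[kept]}\t{r:.4f}\n")
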