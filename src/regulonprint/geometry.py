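"""Bis-chelate coordination geometry from small-molecule coordinates.

For a metal centre M chelated by two bidentate N,N ligands, the two numbers
that summarise the distortion from ideal tetrahedral coordination are

* the *bite angle* of each ligand — the N-M-N angle subtended at the metal
  by one ligand's donor pair (90 deg for an ideal tetrahedral bis-chelate,
  smaller for a constrained ring), and
* the *chelate-plane dihedral* — the angle between the two planes each
  defined exactly by the metal and one donor pair, folded into [0, 90] deg
  (90 deg for perpendicular chelates, 0 for a coplanar arrangement).

Structures are read from XYZ or small-molecule CIF files; donors are
assigned to ligands either by explicit ligand labels or, when absent, by
exhaustive pairing that minimises the within-pair donor-donor distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "StructureModel",
    "ChelateAssignment",
    "ChelateGeometry",
    "load_structure",
    "write_xyz",
    "find_coordination",
    "chelate_geometry",
    "analyze_structure",
]


@dataclass
class StructureModel:
    """Atoms of a small-molecule structure in Cartesian angstroms."""

    elements: list[str]
    labels: list[str]
    ligand_ids: list[str | None]
    coords: np.ndarray  # (n_atoms, 3)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not (len(self.elements) == len(self.labels)
                == len(self.ligand_ids) == self.coords.shape[0]):
            raise ValueError("atom field lengths disagree")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.elements)


def load_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read an XYZ or small-molecule CIF file.

    XYZ files are parsed fully (element + Cartesian coordinates; labels are
    element + serial, no ligand ids).  CIF files are read through gemmi's
    small-structure reader: atom-site labels, fractional coordinates
    orthogonalised via the cell parameters.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return _load_xyz(path)
    if fmt == "cif":
        return _load_cif(path)
    raise ValueError(f"unsupported structure format: {fmt!r}")


def _load_xyz(path: Path) -> StructureModel:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed XYZ header") from exc
    body = lines[2:2 + n]
    if len(body) < n:
        raise ValueError(f"{path}: XYZ declares {n} atoms, found {len(body)}")
    elements, coords = [], []
    for i, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed XYZ atom line {i + 3}")
        elements.append(parts[0])
        coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    labels = [f"{el}{i + 1}" for i, el in enumerate(elements)]
    return StructureModel(elements=elements, labels=labels,
                          ligand_ids=[None] * n, coords=np.array(coords),
                          provenance=f"{path}:xyz")


def _load_cif(path: Path) -> StructureModel:
    import gemmi

    small = gemmi.read_small_structure(str(path))
    if not small.sites:
        raise ValueError(f"{path}: no atom sites in CIF")
    elements, labels, ligand_ids, coords = [], [], [], []
    for site in small.sites:
        pos = small.cell.orthogonalize(site.fract)
        elements.append(site.element.name)
        labels.append(site.label)
        # residue-style suffix (e.g. N1A / N1B) distinguishes ligands if present
        ligand_ids.append(site.label[-1] if site.label and site.label[-1].isalpha()
                          and len(site.label) > 1 else None)
        coords.append([pos.x, pos.y, pos.z])
    return StructureModel(elements=elements, labels=labels,
                          ligand_ids=ligand_ids, coords=np.array(coords),
                          provenance=f"{path}:cif")


def write_xyz(structure: StructureModel, path: str | Path,
              comment: str = "") -> None:
    path = Path(path)
    lines = [str(len(structure)), comment]
    for el, xyz in zip(structure.elements, structure.coords):
        lines.append(f"{el} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
    path.write_text("\n".join(lines) + "\n")


@dataclass
class ChelateAssignment:
    """One metal centre with its four donors grouped into two ligand pairs."""

    center_label: str
    center_xyz: np.ndarray
    pair_labels: tuple[tuple[str, str], tuple[str, str]]
    pair_xyz: tuple[np.ndarray, np.ndarray]  # each (2, 3)


def find_coordination(structure: StructureModel, center: str = "Cu",
                      donor: str = "N", cutoff: float = 2.5):
    """Assign donors within ``cutoff`` of each metal centre into chelate pairs.

    Pairing uses explicit ligand ids when every donor carries one and they
    split 2+2; otherwise the three possible pairings of four donors are
    enumerated and the one minimising the summed within-pair donor-donor
    distance is chosen.  Centres without exactly four donors are skipped
    and reported in the second return value.

    Returns ``(assignments, skipped)`` with ``skipped`` a list of
    ``(center_label, n_donors)``.
    """
    centers = [i for i, el in enumerate(structure.elements) if el == center]
    if not centers:
        raise ValueError(f"no {center} centre in structure")
    donors = [i for i, el in enumerate(structure.elements) if el == donor]
    assignments, skipped = [], []
    for ci in centers:
        cxyz = structure.coords[ci]
        near = [di for di in donors
                if np.linalg.norm(structure.coords[di] - cxyz) <= cutoff]
        if len(near) != 4:
            skipped.append((structure.labels[ci], len(near)))
            continue
        pairs = _pair_donors(structure, near)
        assignments.append(ChelateAssignment(
            center_label=structure.labels[ci],
            center_xyz=cxyz,
            pair_labels=tuple(tuple(structure.labels[i] for i in p) for p in pairs),
            pair_xyz=tuple(structure.coords[list(p)] for p in pairs),
        ))
    return assignments, skipped


def _pair_donors(structure: StructureModel, near: list[int]):
    ids = [structure.ligand_ids[i] for i in near]
    if all(v is not None for v in ids) and len(set(ids)) == 2:
        groups: dict[str, list[int]] = {}
        for i, v in zip(near, ids):
            groups.setdefault(v, []).append(i)
        pair_a, pair_b = groups.values()
        if len(pair_a) == 2 and len(pair_b) == 2:
            return tuple(pair_a), tuple(pair_b)
    # exhaustive over the 3 pairings of 4 donors
    a, b, c, d = near
    candidates = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]

    def cost(pairing):
        return sum(np.linalg.norm(structure.coords[p[0]] - structure.coords[p[1]])
                   for p in pairing)

    return min(candidates, key=cost)


@dataclass
class ChelateGeometry:
    """Bite angles and chelate-plane dihedral of one bis-chelate complex."""

    center_label: str
    bite_angles_deg: tuple[float, float]
    dihedral_deg: float
    distances: tuple[float, float, float, float]

    @property
    def mean_bite_deg(self) -> float:
        return float(np.mean(self.bite_angles_deg))


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def chelate_geometry(assignment: ChelateAssignment) -> ChelateGeometry:
    """Bite angles (one per ligand) and the inter-plane dihedral in [0, 90] deg.

    Each chelate plane is defined exactly by the metal and its two donors;
    the dihedral is the angle between the two plane normals folded so that
    normal sign is immaterial.  A collinear metal-donor-donor triple leaves
    the plane undefined and raises ``ValueError``.
    """
    cu = assignment.center_xyz
    bites, normals, dists = [], [], []
    for pair in assignment.pair_xyz:
        v1, v2 = pair[0] - cu, pair[1] - cu
        bites.append(_angle_deg(v1, v2))
        normal = np.cross(v1, v2)
        norm = np.linalg.norm(normal)
        if norm < 1e-9 * np.linalg.norm(v1) * np.linalg.norm(v2):
            raise ValueError(
                f"collinear donor pair at {assignment.center_label}: plane undefined")
        normals.append(normal / norm)
        dists.extend([float(np.linalg.norm(v1)), float(np.linalg.norm(v2))])
    cosd = abs(float(np.dot(normals[0], normals[1])))
    dihedral = math.degrees(math.acos(min(1.0, cosd)))
    return ChelateGeometry(
        center_label=assignment.center_label,
        bite_angles_deg=(bites[0], bites[1]),
        dihedral_deg=dihedral,
        distances=tuple(dists),
    )


def analyze_structure(structure: StructureModel, center: str = "Cu",
                      donor: str = "N", cutoff: float = 2.5):
    """Per-complex geometries plus the across-complex means.

    Returns ``(geometries, summary)`` where summary holds ``mean_bite_deg``
    and ``mean_dihedral_deg`` over all analysable complexes in the file.
    """
    assignments, skipped = find_coordination(structure, center, donor, cutoff)
    geometries = [chelate_geometry(a) for a in assignments]
    if geometries:
        summary = {
            "n_complexes": len(geometries),
            "mean_bite_deg": float(np.mean([g.mean_bite_deg for g in geometries])),
            "mean_dihedral_deg": float(np.mean([g.dihedral_deg for g in geometries])),
            "skipped": skipped,
        }
    else:
        summary = {"n_complexes": 0, "skipped": skipped}
    return geometries, summary
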