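"""File formats and result reports.

Readers/writers for the Gaussian cube volumetric format, the classic AIM
``.wfn`` wavefunction format (Cartesian GTO primitives, type codes 1–20,
i.e. up to f functions), a small declarative atom-group configuration
format, and structured result reports.

All coordinates are stored internally in bohr.  Cube files whose axis
voxel counts are positive are interpreted as bohr (the common dialect);
negative counts flag ångström axes and are converted on read.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ANGSTROM_TO_BOHR,
    symbol_for_z,
)

__all__ = [
    "MolecularGeometry",
    "DensityField",
    "WfnData",
    "GroupSpec",
    "ResultsReport",
    "CubeFormatError",
    "WfnFormatError",
    "GroupConfigError",
    "read_cube",
    "write_cube",
    "read_wfn",
    "read_group_config",
    "write_report",
]


class CubeFormatError(ValueError):
    """Raised when a cube file does not conform to the standard layout."""


class WfnFormatError(ValueError):
    """Raised when a .wfn file does not conform to the AIM standard."""


class GroupConfigError(ValueError):
    """Raised when a group configuration is malformed or non-exhaustive."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MolecularGeometry:
    """Nuclei of a molecule: symbols, atomic numbers and positions (bohr)."""

    symbols: list[str]
    numbers: np.ndarray        # (natoms,) int
    positions: np.ndarray      # (natoms, 3) float, bohr

    def __post_init__(self) -> None:
        self.numbers = np.asarray(self.numbers, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.natoms < 1:
            raise ValueError("geometry needs at least one atom")
        if np.any(self.numbers < 1):
            raise ValueError("atomic numbers must be >= 1")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions must be finite")
        if len(self.symbols) != self.natoms:
            raise ValueError("symbol/number count mismatch")

    @property
    def natoms(self) -> int:
        return len(self.numbers)

    def close_to(self, other: "MolecularGeometry", tol: float = 1e-6) -> bool:
        return (
            self.natoms == other.natoms
            and bool(np.all(self.numbers == other.numbers))
            and bool(np.allclose(self.positions, other.positions, atol=tol))
        )


@dataclass
class DensityField:
    """Scalar field on a regular 3-D grid with its molecular geometry.

    ``values[i, j, k]`` lives at ``origin + i·axes[0] + j·axes[1] + k·axes[2]``
    (x-outer / z-inner ordering, as in cube files).  Units are
    electrons·bohr⁻³ for densities; signed fields (density differences) are
    equally valid.
    """

    origin: np.ndarray        # (3,) bohr
    axes: np.ndarray          # (3, 3) bohr per voxel step
    values: np.ndarray        # (n1, n2, n3)
    geometry: MolecularGeometry

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 3-D array")
        if abs(np.linalg.det(self.axes)) < 1e-30:
            raise ValueError("axes matrix is singular")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    def same_grid(self, other: "DensityField", tol: float = 1e-9) -> str | None:
        """Return the name of the first differing grid attribute, or None."""
        if self.shape != other.shape:
            return "shape"
        if not np.allclose(self.origin, other.origin, atol=tol):
            return "origin"
        if not np.allclose(self.axes, other.axes, atol=tol):
            return "axes"
        return None

    # --- grid integration (used as the "integrator" for grid-path runs) ---

    def integrate(self, values: np.ndarray) -> float:
        """∫ v(r) dr by the midpoint rule over voxels."""
        return float(np.sum(values)) * self.voxel_volume

    def moment(self, values: np.ndarray) -> np.ndarray:
        """∫ r v(r) dr (bohr units), without materialising a point cloud."""
        v = np.asarray(values)
        n1, n2, n3 = v.shape
        total = np.sum(v)
        s1 = np.einsum("i,ijk->", np.arange(n1, dtype=float), v)
        s2 = np.einsum("j,ijk->", np.arange(n2, dtype=float), v)
        s3 = np.einsum("k,ijk->", np.arange(n3, dtype=float), v)
        m = (
            self.origin * total
            + self.axes[0] * s1
            + self.axes[1] * s2
            + self.axes[2] * s3
        )
        return m * self.voxel_volume

    def voxel_centers(self) -> np.ndarray:
        """All voxel positions as an (N, 3) array in value-array order."""
        n1, n2, n3 = self.shape
        i, j, k = np.meshgrid(
            np.arange(n1), np.arange(n2), np.arange(n3), indexing="ij"
        )
        idx = np.stack([i, j, k], axis=-1).reshape(-1, 3).astype(float)
        return self.origin + idx @ self.axes


@dataclass
class WfnData:
    """Cartesian-GTO wavefunction: primitives plus occupied MOs.

    Primitive ``p`` is ``x^a y^b z^c exp(-α r²)`` centred on
    ``geometry.positions[centers[p]]`` with the Cartesian powers implied by
    the AIM type code (1=s, 2–4=p, 5–10=d, 11–20=f).  MO coefficients are
    stored as read: in the .wfn convention they already absorb primitive
    normalisation.
    """

    geometry: MolecularGeometry
    centers: np.ndarray        # (nprim,) 0-based center index
    type_codes: np.ndarray     # (nprim,) AIM codes 1..20
    exponents: np.ndarray      # (nprim,) bohr^-2
    occupations: np.ndarray    # (nmo,)
    energies: np.ndarray       # (nmo,) hartree
    coefficients: np.ndarray   # (nmo, nprim)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=int)
        self.type_codes = np.asarray(self.type_codes, dtype=int)
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.occupations = np.asarray(self.occupations, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        nprim = len(self.exponents)
        if np.any(self.centers < 0) or np.any(self.centers >= self.geometry.natoms):
            raise WfnFormatError("primitive center index out of range")
        bad = (self.type_codes < 1) | (self.type_codes > 20)
        if np.any(bad):
            raise WfnFormatError(
                f"type code {int(self.type_codes[bad][0])} outside 1-20: "
                "g and higher functions unsupported"
            )
        if self.coefficients.shape != (len(self.occupations), nprim):
            raise WfnFormatError("coefficient matrix shape mismatch")
        if np.any(self.occupations < 0):
            raise WfnFormatError("MO occupations must be >= 0")
        if float(np.sum(self.occupations)) <= 0:
            raise WfnFormatError("total MO occupation must be positive")

    @property
    def nprims(self) -> int:
        return len(self.exponents)

    @property
    def nmos(self) -> int:
        return len(self.occupations)


@dataclass
class GroupSpec:
    """Named, disjoint, exhaustive grouping of atoms (1-based indices)."""

    names: list[str]
    members: list[list[int]]   # 1-based atom indices per group
    natoms: int

    def __post_init__(self) -> None:
        if len(self.names) != len(self.members):
            raise GroupConfigError("name/member list length mismatch")
        if len(set(self.names)) != len(self.names):
            raise GroupConfigError("group names must be unique")
        seen: dict[int, str] = {}
        for name, idxs in zip(self.names, self.members):
            for i in idxs:
                if not 1 <= i <= self.natoms:
                    raise GroupConfigError(
                        f"atom index {i} in group '{name}' out of range "
                        f"1..{self.natoms}"
                    )
                if i in seen:
                    raise GroupConfigError(
                        f"atom {i} assigned twice (groups '{seen[i]}' and "
                        f"'{name}')"
                    )
                seen[i] = name
        missing = sorted(set(range(1, self.natoms + 1)) - set(seen))
        if missing:
            raise GroupConfigError(
                f"groups must collectively include all atoms; atom(s) "
                f"{missing} unassigned"
            )

    @property
    def nsub(self) -> int:
        return len(self.names)

    def atom_to_group(self) -> np.ndarray:
        """(natoms,) array mapping 0-based atom index -> group index."""
        out = np.empty(self.natoms, dtype=int)
        for g, idxs in enumerate(self.members):
            for i in idxs:
                out[i - 1] = g
        return out

    @classmethod
    def per_atom(cls, geometry: MolecularGeometry) -> "GroupSpec":
        names = [
            f"{sym}{i + 1}" for i, sym in enumerate(geometry.symbols)
        ]
        return cls(names, [[i + 1] for i in range(geometry.natoms)],
                   geometry.natoms)


@dataclass
class ResultsReport:
    """Structured record of a CT analysis, mirroring the reported tables.

    Every numeric entry carries explicit units (e, Å, D or dimensionless)
    in its key name.
    """

    transition: str
    global_block: dict = field(default_factory=dict)
    group_block: list[dict] = field(default_factory=list)
    matrices_block: dict = field(default_factory=dict)
    diagnostics_block: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "transition": self.transition,
            "sign_convention": "GS-minus-EX (positive = depletion)",
            "global": self.global_block,
            "groups": self.group_block,
            "matrices": self.matrices_block,
            "diagnostics": self.diagnostics_block,
        }


# ---------------------------------------------------------------------------
# cube format
# ---------------------------------------------------------------------------

def read_cube(path: str) -> tuple[MolecularGeometry, DensityField]:
    """Read a Gaussian cube file (2 comments, natoms+origin, 3 axis lines,
    atom block, values in x-outer/z-inner order)."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    if len(lines) < 6:
        raise CubeFormatError(f"{path}: truncated header")
    try:
        head = lines[2].split()
        natoms = int(head[0])
        origin = np.array([float(x) for x in head[1:4]])
    except (IndexError, ValueError) as exc:
        raise CubeFormatError(f"{path}: bad natoms/origin line") from exc
    if natoms < 0:
        raise CubeFormatError(
            f"{path}: negative atom count ({natoms}) flags the orbital-ID "
            "cube dialect, which is an unsupported dialect here"
        )
    shape = []
    axes = np.zeros((3, 3))
    for ax in range(3):
        parts = lines[3 + ax].split()
        n = int(parts[0])
        vec = np.array([float(x) for x in parts[1:4]])
        if n < 0:
            # negative count flags ångström axis units
            n = -n
            vec = vec * ANGSTROM_TO_BOHR
        if n < 1:
            raise CubeFormatError(f"{path}: axis {ax} has zero voxels")
        shape.append(n)
        axes[ax] = vec
    symbols, numbers, positions = [], [], []
    for a in range(natoms):
        parts = lines[6 + a].split()
        z = int(float(parts[0]))
        numbers.append(z)
        symbols.append(symbol_for_z(z))
        positions.append([float(x) for x in parts[2:5]])
    geometry = MolecularGeometry(symbols, np.array(numbers),
                                 np.array(positions))
    raw = " ".join(lines[6 + natoms:]).split()
    nexpected = shape[0] * shape[1] * shape[2]
    if len(raw) != nexpected:
        raise CubeFormatError(
            f"{path}: expected {nexpected} values, found {len(raw)}"
        )
    values = np.array([float(x) for x in raw]).reshape(shape)
    field = DensityField(origin, axes, values, geometry)
    return geometry, field


def write_cube(geometry: MolecularGeometry, field: DensityField, path: str,
               comment: str = "generated by ctdecomp") -> None:
    """Write a standard-conforming cube file readable by :func:`read_cube`."""
    if not np.all(np.isfinite(field.values)):
        raise ValueError("refusing to write non-finite values to cube file")
    n1, n2, n3 = field.shape
    with open(path, "w") as fh:
        fh.write(comment + "\n")
        fh.write("scalar field, x-outer z-inner value order\n")
        fh.write(
            f"{geometry.natoms:5d} {field.origin[0]:15.8e} "
            f"{field.origin[1]:15.8e} {field.origin[2]:15.8e}\n"
        )
        for n, vec in zip((n1, n2, n3), field.axes):
            fh.write(
                f"{n:5d} {vec[0]:15.8e} {vec[1]:15.8e} {vec[2]:15.8e}\n"
            )
        for z, pos in zip(geometry.numbers, geometry.positions):
            fh.write(
                f"{int(z):5d} {float(z):12.6f} "
                f"{pos[0]:15.8e} {pos[1]:15.8e} {pos[2]:15.8e}\n"
            )
        flat = field.values.reshape(n1 * n2, n3)
        for row in flat:
            for start in range(0, n3, 6):
                chunk = row[start:start + 6]
                fh.write(" ".join(f"{v:16.8e}" for v in chunk) + "\n")


# ---------------------------------------------------------------------------
# AIM .wfn format
# ---------------------------------------------------------------------------

_WFN_HEADER_RE = re.compile(
    r"(\d+)\s+MOL ORBITALS\s+(\d+)\s+PRIMITIVES\s+(\d+)\s+NUCLEI"
)
_WFN_OCC_RE = re.compile(
    r"OCC\s*NO\s*=\s*([-\d.DEde+]+)\s+ORB\.?\s*ENERGY\s*=\s*([-\d.DEde+]+)"
)


def _dfloat(token: str) -> float:
    return float(token.replace("D", "E").replace("d", "e"))


def _ints_after_keyword(lines: list[str], start: int, keyword: str,
                        count: int) -> tuple[list[int], int]:
    vals: list[int] = []
    i = start
    while i < len(lines) and len(vals) < count:
        line = lines[i]
        if keyword in line:
            line = line.split(keyword, 1)[1]
        elif not vals:
            raise WfnFormatError(f"expected '{keyword}' section")
        vals.extend(int(t) for t in line.split())
        i += 1
    return vals, i


def read_wfn(path: str) -> WfnData:
    """Read a classic AIM ``.wfn`` text file (up to f functions)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # header: first line is a free title, second declares the counts
    m = None
    header_idx = 0
    for i, ln in enumerate(lines[:5]):
        m = _WFN_HEADER_RE.search(ln)
        if m:
            header_idx = i
            break
    if not m:
        raise WfnFormatError(f"{path}: missing 'MOL ORBITALS ... PRIMITIVES "
                             "... NUCLEI' header")
    nmo, nprim, nat = (int(g) for g in m.groups())

    symbols, numbers, positions = [], [], []
    i = header_idx + 1
    for _ in range(nat):
        ln = lines[i]
        parts = ln.split()
        sym = parts[0]
        m_charge = re.search(r"CHARGE\s*=\s*([-\d.]+)", ln)
        z = int(float(m_charge.group(1))) if m_charge else 1
        # coordinates are the three floats following the ')' of "(CENTRE n)"
        tail = ln.split(")", 1)[1] if ")" in ln else " ".join(parts[1:])
        floats = re.findall(r"[-+]?\d+\.\d+(?:[EDed][-+]?\d+)?", tail)
        positions.append([_dfloat(x) for x in floats[:3]])
        symbols.append(sym)
        numbers.append(max(z, 1))
        i += 1
    geometry = MolecularGeometry(symbols, np.array(numbers),
                                 np.array(positions))

    centers, i = _ints_after_keyword(lines, i, "CENTRE ASSIGNMENTS", nprim)
    types, i = _ints_after_keyword(lines, i, "TYPE ASSIGNMENTS", nprim)
    if any(t > 20 for t in types):
        raise WfnFormatError(
            f"{path}: type code {max(types)} beyond f shells: "
            "g-functions unsupported"
        )
    exps: list[float] = []
    while i < len(lines) and len(exps) < nprim:
        ln = lines[i]
        if "EXPONENTS" in ln:
            ln = ln.split("EXPONENTS", 1)[1]
        elif not exps:
            raise WfnFormatError(f"{path}: expected EXPONENTS section")
        exps.extend(_dfloat(t) for t in ln.split())
        i += 1

    occs, enes, coefs = [], [], []
    while i < len(lines):
        ln = lines[i]
        if ln.strip().startswith("END DATA"):
            break
        m_occ = _WFN_OCC_RE.search(ln)
        if m_occ:
            occs.append(_dfloat(m_occ.group(1)))
            enes.append(_dfloat(m_occ.group(2)))
            i += 1
            cvec: list[float] = []
            while i < len(lines) and len(cvec) < nprim:
                row = lines[i]
                if _WFN_OCC_RE.search(row) or row.strip().startswith("END DATA"):
                    break
                cvec.extend(_dfloat(t) for t in row.split())
                i += 1
            if len(cvec) != nprim:
                raise WfnFormatError(
                    f"{path}: MO {len(occs)} lists {len(cvec)} coefficients, "
                    f"expected {nprim}"
                )
            coefs.append(cvec)
        else:
            i += 1
    if len(occs) != nmo:
        raise WfnFormatError(
            f"{path}: header declares {nmo} MOs, found {len(occs)}"
        )
    return WfnData(
        geometry=geometry,
        centers=np.array(centers) - 1,
        type_codes=np.array(types),
        exponents=np.array(exps),
        occupations=np.array(occs),
        energies=np.array(enes),
        coefficients=np.array(coefs),
    )


def write_wfn(wfn: WfnData, path: str, title: str = "ctdecomp toy") -> None:
    """Write :class:`WfnData` in the classic AIM .wfn layout."""
    with open(path, "w") as fh:
        fh.write(f" {title}\n")
        fh.write(
            f"GAUSSIAN {wfn.nmos:14d} MOL ORBITALS {wfn.nprims:6d} "
            f"PRIMITIVES {wfn.geometry.natoms:8d} NUCLEI\n"
        )
        for a, (sym, z, pos) in enumerate(
            zip(wfn.geometry.symbols, wfn.geometry.numbers,
                wfn.geometry.positions)
        ):
            fh.write(
                f"  {sym:<2s} {a + 1:4d}    (CENTRE {a + 1:2d}) "
                f"{pos[0]:12.8f} {pos[1]:12.8f} {pos[2]:12.8f}  "
                f"CHARGE = {float(z):4.1f}\n"
            )
        for start in range(0, wfn.nprims, 20):
            chunk = wfn.centers[start:start + 20] + 1
            fh.write("CENTRE ASSIGNMENTS  "
                     + "".join(f"{c:3d}" for c in chunk) + "\n")
        for start in range(0, wfn.nprims, 20):
            chunk = wfn.type_codes[start:start + 20]
            fh.write("TYPE ASSIGNMENTS    "
                     + "".join(f"{c:3d}" for c in chunk) + "\n")
        # full double precision: round-tripped densities must not drift
        for start in range(0, wfn.nprims, 4):
            chunk = wfn.exponents[start:start + 4]
            fh.write("EXPONENTS "
                     + " ".join(f"{e:23.16E}".replace("E", "D")
                                for e in chunk)
                     + "\n")
        for k in range(wfn.nmos):
            fh.write(
                f"MO {k + 1:4d}     MO 0.0        OCC NO = "
                f"{wfn.occupations[k]:12.7f}  ORB. ENERGY = "
                f"{wfn.energies[k]:12.6f}\n"
            )
            row = wfn.coefficients[k]
            for start in range(0, wfn.nprims, 4):
                chunk = row[start:start + 4]
                fh.write(" ".join(f"{c:23.16E}".replace("E", "D")
                                  for c in chunk) + "\n")
        fh.write("END DATA\n")
        fh.write(" THE  HF ENERGY =     0.000000000000 "
                 "THE VIRIAL(-V/T)=   2.00000000\n")


# ---------------------------------------------------------------------------
# group configuration
# ---------------------------------------------------------------------------

PER_ATOM_KEYWORD = "per-atom"


def parse_group_config(text: str, geometry: MolecularGeometry) -> GroupSpec:
    """Parse a declarative group config.

    One group per line, ``Name: i j k`` with 1-based atom indices; ``a-b``
    ranges allowed; ``#`` starts a comment.  The single reserved keyword
    ``per-atom`` expands to one singleton group per atom.
    """
    stripped = text.strip()
    if stripped == PER_ATOM_KEYWORD:
        return GroupSpec.per_atom(geometry)
    names: list[str] = []
    members: list[list[int]] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise GroupConfigError(
                f"line {lineno}: expected 'Name: indices', got {raw!r}"
            )
        name, rest = line.split(":", 1)
        idxs: list[int] = []
        for tok in rest.replace(",", " ").split():
            if "-" in tok[1:]:
                lo, hi = tok.split("-", 1)
                idxs.extend(range(int(lo), int(hi) + 1))
            else:
                idxs.append(int(tok))
        names.append(name.strip())
        members.append(idxs)
    if not names:
        raise GroupConfigError("group config defines no groups")
    return GroupSpec(names, members, geometry.natoms)


def read_group_config(path: str, geometry: MolecularGeometry) -> GroupSpec:
    if path == PER_ATOM_KEYWORD:
        return GroupSpec.per_atom(geometry)
    with open(path) as fh:
        return parse_group_config(fh.read(), geometry)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(report: ResultsReport, path_prefix: str,
                 fmt: str = "both") -> list[str]:
    """Write a report as hierarchical JSON and/or a flat TSV table.

    ``fmt`` is ``"json"``, ``"tsv"`` or ``"both"``.  Returns the paths
    written.  Field order is deterministic.
    """
    import pandas as pd

    written: list[str] = []
    data = report.to_dict()
    if fmt in ("json", "both"):
        jpath = f"{path_prefix}.json"
        with open(jpath, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=False)
            fh.write("\n")
        written.append(jpath)
    if fmt in ("tsv", "both"):
        tpath = f"{path_prefix}.tsv"
        rows = [{"section": "global", "key": k, "value": v}
                for k, v in report.global_block.items()]
        for grp in report.group_block:
            gname = grp.get("group", "?")
            for k, v in grp.items():
                if k == "group":
                    continue
                rows.append({"section": f"group:{gname}", "key": k,
                             "value": v})
        for k, v in report.diagnostics_block.items():
            rows.append({"section": "diagnostics", "key": k, "value": v})
        pd.DataFrame(rows, columns=["section", "key", "value"]).to_csv(
            tpath, sep="\t", index=False
        )
        written.append(tpath)
    if not written:
        raise ValueError(f"unknown report format {fmt!r}")
    return written
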