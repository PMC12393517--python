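"""Ideal coarse-grained DNA duplex builders and minicircle circularization.

The model places three interaction sites per nucleotide (sugar S, phosphate P,
base B) on each of two antiparallel strands.  Every site class traces an ideal
helix around the z axis,

    x_{i,n} = r_i cos(n*dtheta + theta0_i)
    y_{i,n} = r_i sin(n*dtheta + theta0_i)
    z_{i,n} = n*dz + z0_i

parameterized per class i by a radius, an angular offset, and a rise offset,
with a single twist/rise shared by all six classes.  A linear duplex built this
way is bent into a planar, uniformly twisted minicircle by translating its
center of mass onto (0, R, 0) and wrapping the z coordinate into a toroidal
angle, and the bonded topology is closed with a fixed set of junction terms
(6 bonds, 6 angles, 16 dihedrals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .errors import (
    GeometryError,
    LabelingError,
    SequenceError,
    StructuralInputError,
    TopologyError,
)

SITES = ("S", "P", "B")
STRANDS = (1, 2)
#: Fixed per-base-pair atom ordering; atom index = 6*bp + position in this list.
CLASS_ORDER: tuple[tuple[str, int], ...] = (
    ("S", 1), ("P", 1), ("B", 1), ("S", 2), ("P", 2), ("B", 2),
)
_CLASS_POS = {cls: k for k, cls in enumerate(CLASS_ORDER)}

_DNA_ALPHABET = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixParameters:
    """Per-class helix parameters for the six site trajectories.

    Attributes
    ----------
    twist_deg : float
        Twist per base-pair step, degrees, in (0, 360).
    rise_nm : float
        Rise per base-pair step, nm, > 0.
    radius_nm, theta0_deg, z0_nm : dict
        Keyed by (site, strand) with site in {"S","P","B"} and strand in {1,2}.
    """

    twist_deg: float
    rise_nm: float
    radius_nm: dict[tuple[str, int], float]
    theta0_deg: dict[tuple[str, int], float]
    z0_nm: dict[tuple[str, int], float]

    def __post_init__(self) -> None:
        if not (0.0 < self.twist_deg < 360.0):
            raise ValueError(f"twist_deg must be in (0, 360), got {self.twist_deg}")
        if self.rise_nm <= 0.0:
            raise ValueError(f"rise_nm must be > 0, got {self.rise_nm}")
        for cls in CLASS_ORDER:
            for table, name in ((self.radius_nm, "radius_nm"),
                                (self.theta0_deg, "theta0_deg"),
                                (self.z0_nm, "z0_nm")):
                if cls not in table:
                    raise ValueError(f"{name} missing entry for class {cls}")
            if self.radius_nm[cls] <= 0.0:
                raise ValueError(f"radius_nm[{cls}] must be > 0")

    def with_phase_shift(self, phi_deg: float) -> "HelixParameters":
        """Return parameters with every angular offset advanced by ``phi_deg``."""
        shifted = {cls: th + phi_deg for cls, th in self.theta0_deg.items()}
        return replace(self, theta0_deg=shifted)

    def with_twist(self, twist_deg: float) -> "HelixParameters":
        return replace(self, twist_deg=twist_deg)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def table(d: dict) -> dict:
            return {f"{site}{strand}": float(v) for (site, strand), v in d.items()}
        return {
            "twist_deg": float(self.twist_deg),
            "rise_nm": float(self.rise_nm),
            "radius_nm": table(self.radius_nm),
            "theta0_deg": table(self.theta0_deg),
            "z0_nm": table(self.z0_nm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HelixParameters":
        def table(t: dict) -> dict:
            out = {}
            for key, v in t.items():
                site, strand = key[0].upper(), int(key[1])
                out[(site, strand)] = float(v)
            return out
        return cls(
            twist_deg=float(d["twist_deg"]),
            rise_nm=float(d["rise_nm"]),
            radius_nm=table(d["radius_nm"]),
            theta0_deg=table(d["theta0_deg"]),
            z0_nm=table(d["z0_nm"]),
        )


def default_helix_parameters() -> HelixParameters:
    """Load the canonical B-DNA-like parameter set shipped with the package."""
    text = resources.files("minicirc.data").joinpath("default_helix.yaml").read_text()
    return HelixParameters.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BondedTerm:
    """A bond/angle/dihedral: atom indices plus a type label and closure flag."""

    atoms: tuple[int, ...]
    label: str
    closure: bool = False


@dataclass
class LinearDNAModel:
    """An ideal linear duplex: labeled coordinates plus bonded topology.

    Atoms are stored bp-major in the fixed :data:`CLASS_ORDER`; atom index
    ``6*n + k`` is class ``CLASS_ORDER[k]`` of base pair ``n``.  The 5'
    phosphate of each strand's first nucleotide is present but unbonded in the
    linear model ("dangling"); topology closure consumes it.
    """

    sequence: str
    positions: np.ndarray          # (6*n_bp, 3) float, nm
    bonds: list[BondedTerm] = field(default_factory=list)
    angles: list[BondedTerm] = field(default_factory=list)
    dihedrals: list[BondedTerm] = field(default_factory=list)
    params: HelixParameters | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def atom_index(self, bp: int, site: str, strand: int) -> int:
        return 6 * (bp % self.n_bp) + _CLASS_POS[(site, strand)]

    def atom_class(self, index: int) -> tuple[int, str, int]:
        """Return (bp, site, strand) for a flat atom index."""
        site, strand = CLASS_ORDER[index % 6]
        return index // 6, site, strand

    @property
    def bp_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_bp), 6)

    @property
    def site_labels(self) -> np.ndarray:
        return np.tile(np.array([c[0] for c in CLASS_ORDER]), self.n_bp)

    @property
    def strand_labels(self) -> np.ndarray:
        return np.tile(np.array([c[1] for c in CLASS_ORDER]), self.n_bp)

    def all_terms(self) -> list[BondedTerm]:
        return list(self.bonds) + list(self.angles) + list(self.dihedrals)

    def validate(self) -> None:
        n = self.n_atoms
        if n != 6 * self.n_bp:
            raise TopologyError(
                f"expected {6 * self.n_bp} atoms for {self.n_bp} bp, found {n}")
        for term in self.all_terms():
            for a in term.atoms:
                if not (0 <= a < n):
                    raise TopologyError(f"term {term} references missing atom {a}")


@dataclass
class MinicircleModel(LinearDNAModel):
    """A circularized duplex; closure terms are flagged on the bonded lists."""

    radius_nm: float = 0.0

    @property
    def closure_terms(self) -> list[BondedTerm]:
        return [t for t in self.all_terms() if t.closure]

    @property
    def is_closed(self) -> bool:
        return any(t.closure for t in self.all_terms())


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def quantize_twist(intrinsic_twist_deg: float, n_bp: int) -> float:
    """Snap a twist per step to the nearest commensurate value k*360/n_bp.

    Guarantees the total twist over ``n_bp`` steps is an integer multiple of
    360 degrees so the circularized duplex closes seamlessly.  k is the nearest
    integer to ``intrinsic_twist_deg * n_bp / 360`` (at least 1).
    """
    if n_bp < 3:
        raise ValueError(f"n_bp must be >= 3, got {n_bp}")
    if not (0.0 < intrinsic_twist_deg < 360.0):
        raise ValueError(f"intrinsic twist must be in (0, 360), got {intrinsic_twist_deg}")
    k = max(1, math.floor(intrinsic_twist_deg * n_bp / 360.0 + 0.5))
    return k * 360.0 / n_bp


def helix_positions(
    n_bp: int,
    params: HelixParameters,
    twist_deg: float | None = None,
) -> np.ndarray:
    """Evaluate the six helical trajectories: (6*n_bp, 3) bp-major positions."""
    twist = params.twist_deg if twist_deg is None else float(twist_deg)
    n = np.arange(n_bp, dtype=float)
    positions = np.empty((6 * n_bp, 3), dtype=float)
    for k, cls in enumerate(CLASS_ORDER):
        r = params.radius_nm[cls]
        phase = np.radians(n * twist + params.theta0_deg[cls])
        positions[k::6, 0] = r * np.cos(phase)
        positions[k::6, 1] = r * np.sin(phase)
        positions[k::6, 2] = n * params.rise_nm + params.z0_nm[cls]
    return positions


def wrap_cylinder(
    positions: np.ndarray,
    radius_nm: float,
    angle_mode: str = "centerline",
) -> np.ndarray:
    """The raw bend map (x, y, z) -> (x, y*cos t, y*sin t) with t = z/R
    ("centerline") or t = z/y ("per-atom"); no translation is applied.
    Undefined for y <= 0."""
    if angle_mode not in ("centerline", "per-atom"):
        raise ValueError(f"unknown angle_mode {angle_mode!r}")
    R = float(radius_nm)
    if R <= 0:
        raise GeometryError(f"radius must be > 0, got {R}")
    pos = np.asarray(positions, dtype=float)
    y = pos[:, 1]
    if np.any(y <= 0.0):
        raise GeometryError(
            "atoms on or across the bending axis (y <= 0); transform undefined")
    t = pos[:, 2] / (R if angle_mode == "centerline" else y)
    return np.column_stack((pos[:, 0], y * np.cos(t), y * np.sin(t)))


def bend_coordinates(
    positions: np.ndarray,
    radius_nm: float,
    angle_mode: str = "centerline",
) -> np.ndarray:
    """Translate the center of mass to (0, R, 0) and wrap z into a toroidal
    angle; see :func:`circularize` for the two angle modes."""
    pos = np.asarray(positions, dtype=float).copy()
    pos += np.array([0.0, float(radius_nm), 0.0]) - pos.mean(axis=0)
    return wrap_cylinder(pos, radius_nm, angle_mode)


def _check_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise SequenceError(f"invalid base characters: {sorted(bad)}")
    return seq


def complement(sequence: str) -> str:
    """Base-paired partner of each position (not reversed: indexed by bp)."""
    return sequence.translate(_COMPLEMENT)


def build_ideal_linear(
    sequence: str,
    params: HelixParameters,
    twist_override: float | None = None,
) -> LinearDNAModel:
    """Build an ideal linear duplex from six helical site trajectories.

    ``twist_override`` replaces the parameter set's twist (typically the output
    of :func:`quantize_twist`).  Intra-strand backbone, base, and stacking
    bonded terms are generated along both strands; inter-strand pairing bonds
    link the bases of each base pair.
    """
    seq = _check_sequence(sequence)
    twist = params.twist_deg if twist_override is None else float(twist_override)
    if not (0.0 < twist < 360.0):
        raise ValueError(f"twist must be in (0, 360), got {twist}")
    n_bp = len(seq)
    positions = helix_positions(n_bp, params, twist)

    model = LinearDNAModel(
        sequence=seq,
        positions=positions,
        params=params.with_twist(twist),
        metadata={"twist_deg": twist, "rise_nm": params.rise_nm,
                  "terminal_phosphates": "dangling-5prime"},
    )
    bonds, angles, dihedrals = _interior_topology(model)
    model.bonds = bonds
    model.angles = angles
    model.dihedrals = dihedrals
    model.validate()
    return model


def _strand_chain(n_bp: int, strand: int) -> list[int]:
    """Base-pair indices in 5'->3' chain order for a strand."""
    return list(range(n_bp)) if strand == 1 else list(range(n_bp - 1, -1, -1))


def _interior_topology(
    model: LinearDNAModel,
) -> tuple[list[BondedTerm], list[BondedTerm], list[BondedTerm]]:
    """All bonded terms of the open duplex.

    Per strand (chain order c0..cL, 5'->3'), with the 5' phosphate P(c0)
    dangling:
      bonds     PS: P(ck)-S(ck) k>=1;  SP: S(ck)-P(ck+1);  SB: S(ck)-B(ck);
                BB-intra: B(ck)-B(ck+1)
      angles    SPS, 3PSB5 (P of own nucleotide), 5PSB3 (P of next)
      dihedrals SPSP, PSPS, SPSB53, SPSB35, PSBB53, PSBB35
    plus one inter-strand BB pairing bond per base pair.
    """
    bonds: list[BondedTerm] = []
    angles: list[BondedTerm] = []
    dihedrals: list[BondedTerm] = []

    for strand in STRANDS:
        c = _strand_chain(model.n_bp, strand)
        L = len(c) - 1

        def S(k: int) -> int:
            return model.atom_index(c[k], "S", strand)

        def P(k: int) -> int:
            return model.atom_index(c[k], "P", strand)

        def B(k: int) -> int:
            return model.atom_index(c[k], "B", strand)

        for k in range(1, L + 1):
            bonds.append(BondedTerm((P(k), S(k)), "PS"))
        for k in range(L):
            bonds.append(BondedTerm((S(k), P(k + 1)), "SP"))
        for k in range(L + 1):
            bonds.append(BondedTerm((S(k), B(k)), "SB"))
        for k in range(L):
            bonds.append(BondedTerm((B(k), B(k + 1)), "BB-intra"))

        for k in range(L):
            angles.append(BondedTerm((S(k), P(k + 1), S(k + 1)), "SPS"))
        for k in range(1, L + 1):
            angles.append(BondedTerm((P(k), S(k), B(k)), "3PSB5"))
        for k in range(L):
            angles.append(BondedTerm((P(k + 1), S(k), B(k)), "5PSB3"))

        for k in range(1, L):
            dihedrals.append(BondedTerm((S(k - 1), P(k), S(k), P(k + 1)), "SPSP"))
            dihedrals.append(BondedTerm((P(k), S(k), P(k + 1), S(k + 1)), "PSPS"))
        for k in range(L):
            dihedrals.append(BondedTerm((S(k), P(k + 1), S(k + 1), B(k + 1)), "SPSB53"))
            dihedrals.append(BondedTerm((S(k + 1), P(k + 1), S(k), B(k)), "SPSB35"))
        for k in range(1, L):
            dihedrals.append(BondedTerm((P(k), S(k), B(k), B(k + 1)), "PSBB53"))
        for k in range(L):
            dihedrals.append(BondedTerm((P(k + 1), S(k + 1), B(k + 1), B(k)), "PSBB35"))

    for bp in range(model.n_bp):
        bonds.append(BondedTerm(
            (model.atom_index(bp, "B", 1), model.atom_index(bp, "B", 2)), "BB-inter"))

    return bonds, angles, dihedrals


# ---------------------------------------------------------------------------
# circularization
# ---------------------------------------------------------------------------

def circularize(
    linear: LinearDNAModel,
    radius_nm: float | None = None,
    angle_mode: str = "centerline",
) -> MinicircleModel:
    """Bend a linear duplex into a planar, uniformly twisted minicircle.

    The molecule is translated so its center of mass sits at (0, R, 0), then
    each atom (x, y, z) is mapped to (x, y*cos(t), y*sin(t)).  With
    ``angle_mode="centerline"`` the toroidal angle is t = z/R, which closes the
    duplex seamlessly for commensurate twist; ``angle_mode="per-atom"`` uses
    the literal t = z/y, which preserves each atom's own arc length but leaves
    a junction gap for off-centerline atoms.  The x coordinate and the radial
    distance sqrt(y'^2 + z'^2) = y of every atom are preserved exactly.

    If ``radius_nm`` is omitted, R = n_bp * rise / (2*pi), the unique radius
    closing the centerline.
    """
    if angle_mode not in ("centerline", "per-atom"):
        raise ValueError(f"unknown angle_mode {angle_mode!r}")
    if linear.params is None:
        raise GeometryError("model carries no helix parameters; pass radius_nm")
    rise = linear.params.rise_nm
    R = linear.n_bp * rise / (2.0 * math.pi) if radius_nm is None else float(radius_nm)
    bent = bend_coordinates(linear.positions, R, angle_mode)

    meta = dict(linear.metadata)
    meta.update({"radius_nm": R, "angle_mode": angle_mode})
    return MinicircleModel(
        sequence=linear.sequence,
        positions=bent,
        bonds=list(linear.bonds),
        angles=list(linear.angles),
        dihedrals=list(linear.dihedrals),
        params=linear.params,
        metadata=meta,
        radius_nm=R,
    )


# ---------------------------------------------------------------------------
# topology closure
# ---------------------------------------------------------------------------

def close_topology(mini: MinicircleModel) -> MinicircleModel:
    """Add the junction bonded terms that make the duplex covalently closed.

    Adds exactly 6 bonds (SP, PS, BB-intra per strand), 6 angles (SPS, 3PSB5,
    5PSB3 per strand), and 16 dihedrals (two SPSP, two PSPS, one each of
    SPSB53, SPSB35, PSBB53, PSBB35 per strand) between the end atoms,
    consuming each strand's dangling 5' phosphate.
    """
    if mini.is_closed:
        raise TopologyError("closure terms already present (double closure)")

    bonds = list(mini.bonds)
    angles = list(mini.angles)
    dihedrals = list(mini.dihedrals)

    for strand in STRANDS:
        c = _strand_chain(mini.n_bp, strand)
        L = len(c) - 1

        def S(k: int) -> int:
            return mini.atom_index(c[k], "S", strand)

        def P(k: int) -> int:
            return mini.atom_index(c[k], "P", strand)

        def B(k: int) -> int:
            return mini.atom_index(c[k], "B", strand)

        J = P(0)  # dangling 5' phosphate: becomes the junction phosphate

        bonds.append(BondedTerm((S(L), J), "SP", closure=True))
        bonds.append(BondedTerm((J, S(0)), "PS", closure=True))
        bonds.append(BondedTerm((B(L), B(0)), "BB-intra", closure=True))

        angles.append(BondedTerm((S(L), J, S(0)), "SPS", closure=True))
        angles.append(BondedTerm((J, S(0), B(0)), "3PSB5", closure=True))
        angles.append(BondedTerm((J, S(L), B(L)), "5PSB3", closure=True))

        dihedrals.append(BondedTerm((S(L - 1), P(L), S(L), J), "SPSP", closure=True))
        dihedrals.append(BondedTerm((S(L), J, S(0), P(1)), "SPSP", closure=True))
        dihedrals.append(BondedTerm((P(L), S(L), J, S(0)), "PSPS", closure=True))
        dihedrals.append(BondedTerm((J, S(0), P(1), S(1)), "PSPS", closure=True))
        dihedrals.append(BondedTerm((S(L), J, S(0), B(0)), "SPSB53", closure=True))
        dihedrals.append(BondedTerm((S(0), J, S(L), B(L)), "SPSB35", closure=True))
        dihedrals.append(BondedTerm((J, S(0), B(0), B(L)), "PSBB53", closure=True))
        dihedrals.append(BondedTerm((J, S(L), B(L), B(0)), "PSBB35", closure=True))

    out = MinicircleModel(
        sequence=mini.sequence,
        positions=mini.positions,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        params=mini.params,
        metadata=dict(mini.metadata),
        radius_nm=mini.radius_nm,
    )
    out.validate()
    return out


def build_minicircle(
    sequence: str,
    params: HelixParameters | None = None,
    radius_nm: float | None = None,
    angle_mode: str = "centerline",
) -> MinicircleModel:
    """Convenience pipeline: quantize twist, build, circularize, close."""
    params = default_helix_parameters() if params is None else params
    twist = quantize_twist(params.twist_deg, len(_check_sequence(sequence)))
    linear = build_ideal_linear(sequence, params, twist_override=twist)
    return close_topology(circularize(linear, radius_nm, angle_mode))


# ---------------------------------------------------------------------------
# parameter derivation
# ---------------------------------------------------------------------------

def _circmean_rad(angles: np.ndarray) -> float:
    return math.atan2(float(np.mean(np.sin(angles))), float(np.mean(np.cos(angles))))


def derive_helix_parameters(reference: LinearDNAModel) -> HelixParameters:
    """Recover per-class helix parameters from an axis-aligned linear duplex.

    Sugar twist/rise/radius come from successive strand-1 sugar positions;
    every other class is located relative to the sugar of the same base pair
    (its local frame) and the relative offsets averaged over all interior base
    pairs.  Exact round trip for models produced by :func:`build_ideal_linear`.
    """
    n_bp = reference.n_bp
    if n_bp < 3:
        raise StructuralInputError(f"need >= 3 base pairs, got {n_bp}")
    if reference.positions.shape[0] != 6 * n_bp:
        raise LabelingError(
            f"expected {6 * n_bp} atoms (6 per bp), got {reference.positions.shape[0]}")
    pos = reference.positions
    if not np.all(np.isfinite(pos)):
        raise StructuralInputError("non-finite coordinates in reference")

    by_class = {cls: pos[k::6] for k, cls in enumerate(CLASS_ORDER)}

    sug = by_class[("S", 1)]
    phi = np.unwrap(np.arctan2(sug[:, 1], sug[:, 0]))
    n = np.arange(n_bp, dtype=float)
    design = np.column_stack([n, np.ones(n_bp)])
    (twist_rad, theta0_s1), *_ = np.linalg.lstsq(design, phi, rcond=None)
    (rise, z0_s1), *_ = np.linalg.lstsq(design, sug[:, 2], rcond=None)
    twist_rad, theta0_s1 = float(twist_rad), float(theta0_s1)
    rise, z0_s1 = float(rise), float(z0_s1)
    if twist_rad <= 0:
        # left-handed or degenerate reference
        raise StructuralInputError("non-positive mean twist in reference sugars")
    if rise <= 0:
        raise StructuralInputError("non-positive mean rise in reference sugars")

    interior = slice(1, n_bp - 1)

    radius: dict[tuple[str, int], float] = {}
    theta0: dict[tuple[str, int], float] = {}
    z0: dict[tuple[str, int], float] = {}

    radius[("S", 1)] = float(np.mean(np.hypot(sug[:, 0], sug[:, 1])))
    theta0[("S", 1)] = math.degrees(theta0_s1)
    z0[("S", 1)] = z0_s1

    phi_s = np.arctan2(sug[:, 1], sug[:, 0])
    for cls in CLASS_ORDER:
        if cls == ("S", 1):
            continue
        p = by_class[cls]
        radius[cls] = float(np.mean(np.hypot(p[interior, 0], p[interior, 1])))
        dphi = np.arctan2(p[:, 1], p[:, 0]) - phi_s
        theta0[cls] = math.degrees(theta0_s1 + _circmean_rad(dphi[interior]))
        z0[cls] = z0_s1 + float(np.mean(p[interior, 2] - sug[interior, 2]))

    return HelixParameters(
        twist_deg=math.degrees(twist_rad),
        rise_nm=rise,
        radius_nm=radius,
        theta0_deg={k: _wrap_deg(v) for k, v in theta0.items()},
        z0_nm=z0,
    )


def _wrap_deg(a: float) -> float:
    """Wrap to (-180, 180]."""
    w = -((-a + 180.0) % 360.0 - 180.0)
    return 180.0 if w == -180.0 else w


def closure_gap(mini: MinicircleModel) -> float:
    """Largest distance between a bp-0 atom and the image of its virtual
    bp-n_bp continuation under the same bend — 0 for a seamless junction."""
    if mini.params is None:
        raise GeometryError("model carries no helix parameters")
    p = mini.params
    n_bp = mini.n_bp
    R = mini.radius_nm
    mode = mini.metadata.get("angle_mode", "centerline")

    # rebuild the pre-transform coordinates of bp 0 and virtual bp n_bp
    lin = build_ideal_linear(mini.sequence, p)
    com = lin.positions.mean(axis=0)
    shift = np.array([0.0, R, 0.0]) - com

    def bent(bp_n: float, cls: tuple[str, int]) -> np.ndarray:
        r = p.radius_nm[cls]
        phase = math.radians(bp_n * p.twist_deg + p.theta0_deg[cls])
        raw = np.array([r * math.cos(phase), r * math.sin(phase),
                        bp_n * p.rise_nm + p.z0_nm[cls]]) + shift
        t = raw[2] / (R if mode == "centerline" else raw[1])
        return np.array([raw[0], raw[1] * math.cos(t), raw[1] * math.sin(t)])

    return max(float(np.linalg.norm(bent(0, cls) - bent(n_bp, cls)))
               for cls in CLASS_ORDER)
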