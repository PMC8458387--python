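"""Blade geometry of symmetric beta-propeller structures.

An n-bladed propeller is characterised here by four marker C-alpha atoms
per blade — p1, p2 on the innermost strand (beta-1) and q1, q2 on beta-3 —
and the derived quantities:

* a, b      : radial distances of p1, p2 from the central symmetry axis (A)
* c, d, e, f: distances between corresponding markers of cyclically
              subsequent blades (p1-p1', p2-p2', q1-q1', q2-q2') (A)
* alpha     : per-blade rotation about the axis, 360/n for exact symmetry
* beta      : dihedral twist of the beta-1 strand relative to the axis
              plane through p1
* gamma     : internal dihedral twist between beta-1 and beta-3
* delta     : tilt of the beta-1 strand against the axis, in [0, 90] deg

The symmetry axis is detected from the rotations that superpose each blade
onto the next (Kabsch least-squares superposition; axis and angle read off
the rotation matrix), so no symmetry information beyond the blade ranges is
required.  For a regular arrangement the inter-blade marker distances are
chords of a regular n-gon: c = 2 a sin(180/n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import linregress

__all__ = [
    "CoordinateModel",
    "BladeSet",
    "ReferencePoints",
    "SymmetryFrame",
    "GeometryParams",
    "RegressionResult",
    "AsymmetryError",
    "kabsch_superpose",
    "rotation_axis_angle",
    "detect_symmetry_frame",
    "assign_reference_points",
    "compute_blade_geometry",
    "blade_rmsd_matrix",
    "chord_from_radius",
    "regress_vs_blade_number",
    "signed_dihedral",
    "point_line_distance",
]


class AsymmetryError(RuntimeError):
    """Per-blade rotation axes disagree; structure not rotationally symmetric."""


@dataclass
class CoordinateModel:
    """C-alpha records of one structure model.

    Parallel arrays over residues: chain id, residue number, insertion code
    and position (A).  Keys (chain, resnum, icode) are unique.
    """

    chain: np.ndarray
    resnum: np.ndarray
    icode: np.ndarray
    resname: np.ndarray
    coords: np.ndarray  # (N, 3) float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain, self.resnum, self.icode))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, resnum, icode) keys")
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.resnum)

    def ca(self, chain: str, resnum: int, icode: str = "") -> np.ndarray:
        try:
            return self.coords[self._index[(chain, resnum, icode)]]
        except KeyError:
            raise KeyError(f"no C-alpha for chain {chain!r} residue {resnum}{icode}") from None

    def range_coords(self, chain: str, start: int, end: int) -> np.ndarray:
        """C-alpha positions of residues start..end (1-based inclusive), in order."""
        sel = [
            i for i, (ch, rn) in enumerate(zip(self.chain, self.resnum))
            if ch == chain and start <= rn <= end
        ]
        if not sel:
            raise KeyError(f"no residues in {chain}:{start}-{end}")
        return self.coords[sel]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CoordinateModel":
        return CoordinateModel(
            chain=self.chain, resnum=self.resnum, icode=self.icode,
            resname=self.resname,
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
        )


@dataclass(frozen=True)
class BladeSet:
    """Ordered blade residue ranges (chain, start, end), 1-based inclusive."""

    ranges: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        if len(self.ranges) < 3:
            raise ValueError("need >= 3 blades for axis detection")
        for ch, start, end in self.ranges:
            if end - start + 1 < 4:
                raise ValueError(f"blade {ch}:{start}-{end} covers fewer than 4 residues")

    @property
    def n(self) -> int:
        return len(self.ranges)


@dataclass
class ReferencePoints:
    """The four marker C-alpha per blade: p1, p2 on beta-1, q1, q2 on beta-3."""

    p1: np.ndarray  # (n, 3)
    p2: np.ndarray
    q1: np.ndarray
    q2: np.ndarray

    @property
    def n(self) -> int:
        return len(self.p1)


@dataclass
class SymmetryFrame:
    axis_point: np.ndarray
    axis_dir: np.ndarray
    alpha_per_blade: float           # degrees
    step_angles: np.ndarray          # degrees, one per cyclic blade pair

    def __post_init__(self):
        self.axis_dir = np.asarray(self.axis_dir, dtype=float)
        n = np.linalg.norm(self.axis_dir)
        if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-9):
            self.axis_dir = self.axis_dir / n


@dataclass
class GeometryParams:
    """Per-blade values and mean +/- sd of the ten blade-geometry parameters."""

    per_blade: Mapping[str, np.ndarray]
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n: int

    PARAMS = ("a", "b", "c", "d", "e", "f", "alpha", "beta", "gamma", "delta")

    def summary_row(self) -> dict[str, str]:
        out = {}
        for k in self.PARAMS:
            dec = 2 if k in "abcdef" else 1
            out[k] = f"{self.mean[k]:.{dec}f} ± {self.sd[k]:.{dec}f}"
        return out


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    excluded: tuple[str, ...] = ()


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-squares rigid superposition of A onto B (proper rotation only).

    Returns (rotation, translation, rmsd) with b ~ a @ rotation.T + translation.
    Reflections are corrected by flipping the smallest singular direction,
    so the determinant is always +1.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("matched (N, 3) point lists required")
    if len(A) < 3:
        raise ValueError("need >= 3 matched points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    if np.linalg.matrix_rank(H) < 2:
        raise np.linalg.LinAlgError("degenerate geometry: points nearly collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((A0 @ R.T - B0) ** 2, axis=1))))
    return R, t, rmsd


def rotation_axis_angle(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit vector) and angle (degrees) of a proper rotation matrix.

    The axis sign follows the right-hand rule for the returned positive
    angle, read from the skew-symmetric part of R.
    """
    tr = float(np.trace(R))
    angle = math.degrees(math.acos(min(1.0, max(-1.0, (tr - 1.0) / 2.0))))
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        # angle ~ 0 or 180 deg; fall back to the symmetric eigenproblem
        w, v = np.linalg.eigh((R + R.T) / 2.0)
        axis = v[:, np.argmax(w)]
    else:
        axis = axis / norm
    return axis, angle


def detect_symmetry_frame(
    model: CoordinateModel,
    blades: BladeSet,
    max_axis_spread_deg: float = 15.0,
) -> SymmetryFrame:
    """Detect the central rotation axis from consecutive-blade superpositions.

    For each cyclic blade pair (i, i+1) the blades (trimmed to their common
    length from the range start) are superposed and the rotation axis and
    angle extracted; axes are sign-aligned, averaged and renormalised, and
    the axis point solved from the stacked fixed-point equations
    (I - R) p = t in the least-squares sense.  Raises AsymmetryError when
    per-pair axes disagree by more than `max_axis_spread_deg`.
    """
    n = blades.n
    blade_coords = []
    for ch, start, end in blades.ranges:
        blade_coords.append(model.range_coords(ch, start, end))
    axes, angles, rotations, translations = [], [], [], []
    for i in range(n):
        a = blade_coords[i]
        b = blade_coords[(i + 1) % n]
        L = min(len(a), len(b))
        R, t, _ = kabsch_superpose(a[:L], b[:L])
        axis, angle = rotation_axis_angle(R)
        axes.append(axis)
        angles.append(angle)
        rotations.append(R)
        translations.append(t)
    axes = np.asarray(axes)
    # sign-align on the first axis
    for i in range(1, n):
        if np.dot(axes[i], axes[0]) < 0:
            axes[i] = -axes[i]
    mean_axis = axes.mean(axis=0)
    mean_axis /= np.linalg.norm(mean_axis)
    spreads = [math.degrees(math.acos(min(1.0, abs(float(np.dot(ax, mean_axis)))))) for ax in axes]
    if max(spreads) > max_axis_spread_deg:
        raise AsymmetryError(
            f"per-pair rotation axes spread up to {max(spreads):.1f} deg "
            f"(limit {max_axis_spread_deg} deg); structure is not rotationally symmetric"
        )
    # least-squares point on the common axis: stack (I - R_k) p = t_k
    A = np.vstack([np.eye(3) - R for R in rotations])
    b = np.hstack(translations)
    axis_point, *_ = np.linalg.lstsq(A, b, rcond=None)
    return SymmetryFrame(
        axis_point=axis_point,
        axis_dir=mean_axis,
        alpha_per_blade=float(np.mean(angles)),
        step_angles=np.asarray(angles),
    )


def assign_reference_points(
    model: CoordinateModel,
    blades: BladeSet,
    offsets: tuple[int, int, int, int],
) -> ReferencePoints:
    """Select the four marker C-alpha per blade by within-blade offsets.

    offsets are 1-based positions within each blade range, ordered
    (p1, p2, q1, q2).
    """
    if len(offsets) != 4:
        raise ValueError("exactly four offsets (p1, p2, q1, q2) required")
    pts = {k: [] for k in ("p1", "p2", "q1", "q2")}
    for ch, start, end in blades.ranges:
        length = end - start + 1
        for key, off in zip(("p1", "p2", "q1", "q2"), offsets):
            if not 1 <= off <= length:
                raise ValueError(
                    f"offset {off} outside blade {ch}:{start}-{end} (length {length})"
                )
            pts[key].append(model.ca(ch, start + off - 1))
    return ReferencePoints(**{k: np.asarray(v) for k, v in pts.items()})


def point_line_distance(point: np.ndarray, line_point: np.ndarray, line_dir: np.ndarray) -> float:
    v = np.asarray(point) - np.asarray(line_point)
    d = np.asarray(line_dir) / np.linalg.norm(line_dir)
    return float(np.linalg.norm(v - np.dot(v, d) * d))


def signed_dihedral(p0, p1, p2, p3) -> float:
    """IUPAC-signed dihedral of four points about the p1-p2 axis, degrees."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    return math.degrees(math.atan2(y, x))


def compute_blade_geometry(refpoints: ReferencePoints, frame: SymmetryFrame) -> GeometryParams:
    """Derive the a-f distances and alpha-delta angles from marker points.

    All n cyclic blade pairs (including last -> first) contribute to the
    inter-blade distances, since the propeller is a closed ring.
    """
    n = refpoints.n
    P, z = frame.axis_point, frame.axis_dir
    per: dict[str, np.ndarray] = {}
    per["a"] = np.array([point_line_distance(p, P, z) for p in refpoints.p1])
    per["b"] = np.array([point_line_distance(p, P, z) for p in refpoints.p2])
    for key, pts in (("c", refpoints.p1), ("d", refpoints.p2),
                     ("e", refpoints.q1), ("f", refpoints.q2)):
        per[key] = np.array([
            float(np.linalg.norm(pts[(i + 1) % n] - pts[i])) for i in range(n)
        ])
    per["alpha"] = frame.step_angles.copy()
    beta, gamma, delta = [], [], []
    for i in range(n):
        p1, p2 = refpoints.p1[i], refpoints.p2[i]
        q1, q2 = refpoints.q1[i], refpoints.q2[i]
        v = p2 - p1
        nv = np.linalg.norm(v)
        if nv < 1e-9:
            raise ValueError(f"degenerate blade {i}: zero-length strand vector")
        cosd = abs(float(np.dot(v, z))) / nv  # |cos| maps the tilt into [0, 90]
        delta.append(math.degrees(math.acos(min(1.0, cosd))))
        foot = P + np.dot(p1 - P, z) * z  # axis projection of p1
        beta.append(signed_dihedral(foot + z, foot, p1, p2))
        gamma.append(signed_dihedral(p1, p2, q2, q1))
    per["beta"] = np.asarray(beta)
    per["gamma"] = np.asarray(gamma)
    per["delta"] = np.asarray(delta)
    mean = {k: float(np.mean(v)) for k, v in per.items()}
    sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in per.items()}
    return GeometryParams(per_blade=per, mean=mean, sd=sd, n=n)


def blade_rmsd_matrix(model: CoordinateModel, blades: BladeSet) -> np.ndarray:
    """Pairwise C-alpha RMSD between blades after optimal superposition."""
    coords = [model.range_coords(ch, s, e) for ch, s, e in blades.ranges]
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            L = min(len(coords[i]), len(coords[j]))
            _, _, rmsd = kabsch_superpose(coords[i][:L], coords[j][:L])
            out[i, j] = out[j, i] = rmsd
    return out


def chord_from_radius(radius: float, n: int) -> float:
    """Chord length of the regular n-gon with the given circumradius.

    c = 2 R sin(180/n): the distance between equivalent marker atoms of
    neighbouring blades in a perfectly n-fold symmetric ring.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    return 2.0 * radius * math.sin(math.pi / n)


def regress_vs_blade_number(
    values: Sequence[float],
    n_blades: Sequence[int],
    labels: Sequence[str] | None = None,
    exclude: Sequence[str] = (),
) -> RegressionResult:
    """OLS of a geometric parameter against blade count, with exclusions."""
    labels = list(labels) if labels is not None else [str(i) for i in range(len(values))]
    if not (len(values) == len(n_blades) == len(labels)):
        raise ValueError("values, n_blades and labels must have equal length")
    keep = [i for i, lab in enumerate(labels) if lab not in set(exclude)]
    if len(keep) < 3:
        raise ValueError("need >= 3 points after exclusions")
    x = np.asarray([n_blades[i] for i in keep], dtype=float)
    y = np.asarray([values[i] for i in keep], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("undefined slope: all blade numbers identical")
    res = linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), n_points=len(keep),
        excluded=tuple(exclude),
    )
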