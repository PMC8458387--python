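"""Synthetic data generators mirroring the measurement designs of the study
system: CD melting curves (20-85 deg C in 0.2 deg C steps), guanidine
hydrochloride titrations (0-6 M in 0.25 M steps, triplicate), idealised
n-bladed propeller C-alpha models with known ground-truth geometry, and
mutated tandem-repeat families.

Every generator is a pure function of its parameter record; all randomness
flows through an explicit seed via numpy's Generator, and noise is applied
to signals or coordinates only, never to the sampling grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .consensus import AMINO_ACIDS, RepeatAlignment
from .geometry import (
    BladeSet,
    CoordinateModel,
    GeometryParams,
    ReferencePoints,
    SymmetryFrame,
    signed_dihedral,
)
from .stability import DenaturationCurve, chemical_model, thermal_model

__all__ = [
    "ThermalSimParams",
    "ChemicalSimParams",
    "PropellerSimParams",
    "gen_thermal_curve",
    "gen_chemical_curve",
    "gen_ideal_propeller",
    "gen_repeat_family",
    "random_rotation",
]


@dataclass(frozen=True)
class ThermalSimParams:
    """Defaults follow the reported reference-protein melt (v13 variant)."""

    Tm: float = 77.68            # deg C
    dHm: float = -790.0          # kJ/mol (negative = unfolding convention)
    alpha_N: float = 0.0
    beta_N: float = 0.0
    alpha_D: float = 1.0
    beta_D: float = 0.0
    noise_sd: float = 0.01       # signal units
    t_min: float = 20.0
    t_max: float = 85.0
    t_step: float = 0.2
    seed: int = 0

    def grid(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.t_step))
        return self.t_min + self.t_step * np.arange(n + 1)


@dataclass(frozen=True)
class ChemicalSimParams:
    """Defaults follow the reported reference-protein GdnHCl titration."""

    Cm: float = 2.05             # M
    m: float = 9.0               # kJ mol^-1 M^-1
    alpha_N: float = 0.0
    beta_N: float = 0.0
    alpha_D: float = 1.0
    beta_D: float = 0.0
    temperature_K: float = 293.15
    noise_sd: float = 0.02       # fraction units
    replicates: int = 3
    d_min: float = 0.0
    d_max: float = 6.0
    d_step: float = 0.25
    seed: int = 0

    def grid(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.d_step))
        return self.d_min + self.d_step * np.arange(n + 1)


@dataclass(frozen=True)
class PropellerSimParams:
    """Placement parameters of an ideal n-bladed propeller.

    Blade 0's four marker points are placed from radii, heights and azimuth
    offsets (degrees, about the z axis), then copied by rotations of 360/n;
    the derived twist/tilt angles (beta, gamma, delta) are reported in the
    ground-truth record rather than taken as inputs, because the four
    marker positions determine them.  Defaults approximate the seven-bladed
    WRAP-T geometry.
    """

    n: int = 7
    a: float = 5.82              # p1 radius, A
    b: float = 8.51              # p2 radius, A
    rise: float = 6.0            # z of p2 above p1, A
    p2_azimuth_deg: float = 0.0
    rq1: float = 15.3            # q1 radius, A
    rq2: float = 17.4            # q2 radius, A
    q1_z: float = 0.0
    q2_z: float = 6.0
    q1_azimuth_deg: float = 0.0
    q2_azimuth_deg: float = 0.0
    points_per_strand: int = 2   # >= 2; markers sit at strand ends
    noise_sd: float = 0.0        # isotropic coordinate noise, A
    rotation: np.ndarray | None = None   # optional rigid pose
    translation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("n must be >= 3")
        for r in (self.a, self.b, self.rq1, self.rq2):
            if r <= 0:
                raise ValueError("radii must be positive")
        if self.points_per_strand < 2:
            raise ValueError("points_per_strand must be >= 2")


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det +1)."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def gen_thermal_curve(params: ThermalSimParams) -> tuple[DenaturationCurve, ThermalSimParams]:
    """Simulate a CD melt; returns the curve and its ground-truth record."""
    if params.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = params.grid()
    y = thermal_model(t, params.alpha_N, params.beta_N, params.alpha_D,
                      params.beta_D, params.dHm, params.Tm)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        y = y + rng.normal(0.0, params.noise_sd, size=y.shape)
    return DenaturationCurve(axis_kind="temperature", x=t, signal=y), params


def gen_chemical_curve(params: ChemicalSimParams) -> tuple[DenaturationCurve, ChemicalSimParams]:
    """Simulate a replicated denaturant titration with its truth record."""
    if params.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if params.replicates < 1:
        raise ValueError("replicates must be >= 1")
    d = params.grid()
    clean = chemical_model(d, params.alpha_N, params.beta_N, params.alpha_D,
                           params.beta_D, params.m, params.Cm,
                           params.temperature_K)
    rng = np.random.default_rng(params.seed)
    xs, ys, reps = [], [], []
    for r in range(params.replicates):
        y = clean.copy()
        if params.noise_sd > 0:
            y = y + rng.normal(0.0, params.noise_sd, size=y.shape)
        xs.append(d)
        ys.append(y)
        reps.append(np.full(d.shape, r))
    curve = DenaturationCurve(
        axis_kind="denaturant",
        x=np.concatenate(xs),
        signal=np.concatenate(ys),
        replicate_id=np.concatenate(reps),
    )
    return curve, params


def _blade0_markers(p: PropellerSimParams) -> dict[str, np.ndarray]:
    p1 = np.array([p.a, 0.0, 0.0])
    p2 = _rot_z(p.p2_azimuth_deg) @ np.array([p.b, 0.0, 0.0]) + np.array([0.0, 0.0, p.rise])
    q1 = _rot_z(p.q1_azimuth_deg) @ np.array([p.rq1, 0.0, 0.0]) + np.array([0.0, 0.0, p.q1_z])
    q2 = _rot_z(p.q2_azimuth_deg) @ np.array([p.rq2, 0.0, 0.0]) + np.array([0.0, 0.0, p.q2_z])
    return {"p1": p1, "p2": p2, "q1": q1, "q2": q2}


def _truth_geometry(p: PropellerSimParams) -> GeometryParams:
    """Closed-form ground-truth parameters of the ideal construction."""
    mk = _blade0_markers(p)
    z = np.array([0.0, 0.0, 1.0])
    sin_half = math.sin(math.pi / p.n)
    v = mk["p2"] - mk["p1"]
    delta = math.degrees(math.acos(abs(float(np.dot(v, z))) / np.linalg.norm(v)))
    foot = np.array([0.0, 0.0, 0.0])  # axis projection of p1 (p1 at z = 0)
    beta = signed_dihedral(foot + z, foot, mk["p1"], mk["p2"])
    gamma = signed_dihedral(mk["p1"], mk["p2"], mk["q2"], mk["q1"])
    mean = {
        "a": p.a, "b": p.b,
        "c": 2.0 * p.a * sin_half, "d": 2.0 * p.b * sin_half,
        "e": 2.0 * p.rq1 * sin_half, "f": 2.0 * p.rq2 * sin_half,
        "alpha": 360.0 / p.n, "beta": beta, "gamma": gamma, "delta": delta,
    }
    per = {k: np.full(p.n, val) for k, val in mean.items()}
    sd = {k: 0.0 for k in mean}
    return GeometryParams(per_blade=per, mean=mean, sd=sd, n=p.n)


def gen_ideal_propeller(
    params: PropellerSimParams,
) -> tuple[CoordinateModel, BladeSet, ReferencePoints, GeometryParams]:
    """Build an ideal n-fold propeller C-alpha model with known geometry.

    Returns the (optionally posed and noised) model, the blade residue
    ranges, the noise-free marker points in the output frame, and the
    ground-truth geometry of the construction (pose-invariant).  Each blade
    contributes two strand traces of `points_per_strand` C-alpha each: the
    inner strand through p1-p2 and the beta-3 strand through q1-q2.
    """
    mk = _blade0_markers(params)
    k = params.points_per_strand
    fracs = np.linspace(0.0, 1.0, k)
    strand1 = np.outer(1 - fracs, mk["p1"]) + np.outer(fracs, mk["p2"])
    strand3 = np.outer(1 - fracs, mk["q1"]) + np.outer(fracs, mk["q2"])
    blade0 = np.vstack([strand1, strand3])  # residues 1..2k within the blade

    coords, p1s, p2s, q1s, q2s = [], [], [], [], []
    for i in range(params.n):
        Rz = _rot_z(360.0 * i / params.n)
        blade = blade0 @ Rz.T
        coords.append(blade)
        p1s.append(Rz @ mk["p1"])
        p2s.append(Rz @ mk["p2"])
        q1s.append(Rz @ mk["q1"])
        q2s.append(Rz @ mk["q2"])
    coords = np.vstack(coords)
    refs = {
        "p1": np.asarray(p1s), "p2": np.asarray(p2s),
        "q1": np.asarray(q1s), "q2": np.asarray(q2s),
    }

    R = params.rotation if params.rotation is not None else np.eye(3)
    t = params.translation if params.translation is not None else np.zeros(3)
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    coords = coords @ R.T + t
    for key in refs:
        refs[key] = refs[key] @ R.T + t
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        coords = coords + rng.normal(0.0, params.noise_sd, size=coords.shape)

    n_res = len(coords)
    blade_len = 2 * k
    model = CoordinateModel(
        chain=np.array(["A"] * n_res),
        resnum=np.arange(1, n_res + 1),
        icode=np.array([""] * n_res),
        resname=np.array(["ALA"] * n_res),
        coords=coords,
    )
    blades = BladeSet(ranges=tuple(
        ("A", i * blade_len + 1, (i + 1) * blade_len) for i in range(params.n)
    ))
    refpoints = ReferencePoints(**refs)
    return model, blades, refpoints, _truth_geometry(params)


def marker_offsets(params: PropellerSimParams) -> tuple[int, int, int, int]:
    """Within-blade offsets (1-based) of p1, p2, q1, q2 in generated models."""
    k = params.points_per_strand
    return (1, k, k + 1, 2 * k)


def gen_repeat_family(
    consensus: str,
    n_repeats: int,
    substitution_rate: float,
    seed: int = 0,
) -> RepeatAlignment:
    """Mutate a consensus repeat into a family of diverged copies.

    Each site of each repeat is substituted independently with the given
    rate, to a uniformly random *different* residue.
    """
    if not 0.0 <= substitution_rate < 1.0:
        raise ValueError("substitution rate must be in [0, 1)")
    consensus = consensus.upper()
    rng = np.random.default_rng(seed)
    seqs = []
    for _ in range(n_repeats):
        chars = list(consensus)
        hits = np.nonzero(rng.random(len(chars)) < substitution_rate)[0]
        for j in hits:
            choices = [r for r in AMINO_ACIDS if r != chars[j]]
            chars[j] = choices[rng.integers(len(choices))]
        seqs.append("".join(chars))
    return RepeatAlignment.from_sequences(seqs)
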