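"""Published parameter tables for the WRAP-T permutants and the symmetric
designer-propeller series, used as worked-example inputs.

Stability parameters are the reported two-state fits for the four WRAP-T
circular permutants (nv / v31 / v22 / v13, named for the Velcro closure of
the ring-closing blade; v13 carries the natural closure of the 2ymu
template and serves as the reference in all ddG comparisons).  Geometry
parameters are the reported per-structure means for the five designer
propeller families: Tachylectin-2 (PDB 5c2m, n=5), Pizza6 (3ww9, n=6),
WRAP-T (7big, n=7), Tako8 (6g6n, n=8), Cake8 (6tjg, n=8) and Cake9
(6tjh, n=9).
"""

from __future__ import annotations

#: Thermal denaturation fits: melting temperature (deg C) and van't Hoff
#: enthalpy (kJ/mol, unfolding convention dHm < 0).
THERMAL_FITS: dict[str, dict[str, float]] = {
    "nvWRAP-T": {"Tm": 78.33, "Tm_se": 0.06, "dHm": -590.0, "dHm_se": 17.0},
    "v31WRAP-T": {"Tm": 78.63, "Tm_se": 0.09, "dHm": -430.0, "dHm_se": 11.0},
    "v22WRAP-T": {"Tm": 73.80, "Tm_se": 0.03, "dHm": -860.0, "dHm_se": 16.0},
    "v13WRAP-T": {"Tm": 77.68, "Tm_se": 0.03, "dHm": -790.0, "dHm_se": 16.0},
}

#: Chemical (GdnHCl) denaturation fits: m-value (kJ mol^-1 M^-1) and
#: midpoint Cm (M).  v31 resisted denaturation up to 6 M and has no fit.
CHEMICAL_FITS: dict[str, dict[str, float]] = {
    "nvWRAP-T": {"m": 10.0, "m_se": 1.3, "Cm": 2.21, "Cm_se": 0.04},
    "v22WRAP-T": {"m": 28.0, "m_se": 6.0, "Cm": 1.17, "Cm_se": 0.03},
    "v13WRAP-T": {"m": 9.0, "m_se": 1.3, "Cm": 2.05, "Cm_se": 0.05},
}

#: Reference protein for ddG comparisons (the natural Velcro position).
DDG_REFERENCE = "v13WRAP-T"

#: Mean geometric parameters of the symmetric designer propellers:
#: distances in A, angles in degrees.
PROPELLER_GEOMETRY: dict[str, dict[str, float]] = {
    "Tachylectin-2": {"pdb": "5c2m", "n": 5, "a": 7.0, "b": 6.28, "c": 8.19,
                      "d": 7.41, "e": 19.8, "f": 18.7, "alpha": 70.0,
                      "beta": -10.0, "gamma": -22.84, "delta": 11.0},
    "Pizza6": {"pdb": "3ww9", "n": 6, "a": 4.6, "b": 7.1, "c": 4.5,
               "d": 7.2, "e": 14.7, "f": 16.24, "alpha": 60.0,
               "beta": -4.8, "gamma": -29.0, "delta": 14.8},
    "WRAP-T": {"pdb": "7big", "n": 7, "a": 5.82, "b": 8.51, "c": 5.03,
               "d": 7.38, "e": 13.32, "f": 15.1, "alpha": 51.4,
               "beta": -0.7, "gamma": -32.8, "delta": 14.5},
    "Tako8": {"pdb": "6g6n", "n": 8, "a": 7.32, "b": 11.4, "c": 5.6,
              "d": 8.74, "e": 13.2, "f": 15.0, "alpha": 45.0,
              "beta": -9.0, "gamma": -23.8, "delta": 25.0},
    "Cake8": {"pdb": "6tjg", "n": 8, "a": 6.63, "b": 10.85, "c": 5.08,
              "d": 8.30, "e": 13.1, "f": 14.58, "alpha": 45.0,
              "beta": 11.1, "gamma": -44.4, "delta": 28.2},
    "Cake9": {"pdb": "6tjh", "n": 9, "a": 8.34, "b": 12.96, "c": 5.74,
              "d": 8.9, "e": 12.92, "f": 14.43, "alpha": 40.0,
              "beta": 14.0, "gamma": -45.9, "delta": 13.0},
}

#: Labels of the propellers entering the radius-vs-n regression (the
#: five-bladed Tachylectin-2 is the reported outlier and is excluded).
RADIUS_REGRESSION_SET = ("Pizza6", "WRAP-T", "Tako8", "Cake8", "Cake9")


def geometry_series(param: str, labels=None) -> tuple[list[float], list[int], list[str]]:
    """(values, blade counts, labels) for one geometric parameter."""
    labels = list(labels) if labels is not None else list(PROPELLER_GEOMETRY)
    vals = [PROPELLER_GEOMETRY[lab][param] for lab in labels]
    ns = [int(PROPELLER_GEOMETRY[lab]["n"]) for lab in labels]
    return vals, ns, labels
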