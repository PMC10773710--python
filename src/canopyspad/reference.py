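"""Reference parameter sets for maize vertical SPAD profiles.

Default Lorentz-peak parameter triples ``(spad_m, n_m, b)`` for each
nitrogen treatment (N0–N6, 0–400 kg N ha⁻¹) at four growth stages
(V6, V9, R1 silking, R2 blister), representative of field-grown maize
calibrated over a full season.  They drive the synthetic campaign
generator and serve as a realistic parameter bank for examples.

Also defined here: the leaf-position range measurable at each stage
(lower leaves senesce by R1/R2, so counting starts at leaf 6), and the
leaf position whose SPAD is, at each stage, most tightly coupled to
canopy-scale red-edge reflectance (the "sensitive" leaf).
"""

from __future__ import annotations

from .lorentz import LorentzParams

STAGES = ("V6", "V9", "R1", "R2")

N_TREATMENTS = ("N0", "N1", "N2", "N3", "N4", "N5", "N6")

#: Inclusive leaf-position range measured at each stage.
LEAF_RANGES: dict[str, tuple[int, int]] = {
    "V6": (1, 6),
    "V9": (1, 9),
    "R1": (6, 20),
    "R2": (6, 19),
}

#: Leaf position per stage whose SPAD best tracks canopy reflectance.
SENSITIVE_LEAF: dict[str, int] = {"V6": 6, "V9": 4, "R1": 12, "R2": 12}

#: (spad_m, n_m, b) per treatment and stage.
LORENTZ_PARAMS: dict[str, dict[str, LorentzParams]] = {
    treatment: {
        stage: LorentzParams(*triple)
        for stage, triple in zip(STAGES, rows)
    }
    for treatment, rows in {
        "N0": [(39.16, 4, 6.51), (41.80, 4, 7.01), (48.69, 12, 8.24), (47.62, 14, 10.58)],
        "N1": [(42.12, 4, 6.99), (47.94, 4, 8.92), (56.58, 13, 10.56), (57.12, 13, 9.83)],
        "N2": [(40.48, 4, 6.83), (49.55, 4, 8.87), (58.37, 13, 10.26), (57.92, 12, 12.27)],
        "N3": [(41.75, 4, 6.18), (51.92, 5, 8.17), (57.06, 13, 11.49), (55.28, 12, 13.40)],
        "N4": [(46.00, 5, 8.32), (54.40, 5, 8.55), (59.33, 13, 11.09), (59.20, 14, 13.02)],
        "N5": [(47.40, 4, 6.90), (53.89, 4, 8.77), (58.29, 12, 12.87), (58.86, 12, 12.08)],
        "N6": [(47.22, 4, 7.42), (54.40, 4, 10.03), (57.77, 13, 10.94), (58.11, 14, 14.56)],
    }.items()
}
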