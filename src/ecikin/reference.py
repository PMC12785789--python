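"""Reference parameter sets for oak staves at three toast levels.

These constants are the package's default study conditions: the kinetic
parameter sets of the bi-exponential extraction/adsorption model per toast
level, the surface-texture descriptor values measured on toasted stave
images, and the Raman G-band intensities that track carbonisation.  The
synthetic-data generators and the default feature matrix are built from
them, so every stage of the pipeline can be exercised without external
data.

Toast levels correspond to the thermal treatment of barrel staves:
light (185 °C / 60 s), medium (210 °C / 90 s), intense (235 °C / 120 s).
"""

from __future__ import annotations

TOAST_LEVELS: tuple[str, str, str] = ("light", "medium", "intense")

#: Bi-exponential kinetic parameters per toast level.
#: eci_eq [μA/V], amplitude magnitudes a1_mag/a2_mag [μA/V],
#: rate constants k1/k2 [day⁻¹], r2 = coefficient of determination of the
#: original fits (kept for reference, not used by the generators).
KINETIC_REFERENCE: dict[str, dict[str, float]] = {
    "light": {
        "eci_eq": 0.168, "a1_mag": 20.848, "k1": 0.350,
        "a2_mag": 20.651, "k2": 0.332, "r2": 0.874,
    },
    "medium": {
        "eci_eq": 0.185, "a1_mag": 16.810, "k1": 0.356,
        "a2_mag": 16.591, "k2": 0.331, "r2": 0.891,
    },
    "intense": {
        "eci_eq": 0.174, "a1_mag": 8.187, "k1": 0.383,
        "a2_mag": 7.980, "k2": 0.335, "r2": 0.904,
    },
}

#: GLCM texture descriptors of stave-surface photographs per toast level
#: (direction-averaged over 0°/45°/90°/135°, 1-pixel offset, 256 levels).
TEXTURE_REFERENCE: dict[str, dict[str, float]] = {
    "light": {
        "contrast": 252.73, "entropy": 12.32,
        "homogeneity": 0.1824, "correlation": 0.8485,
    },
    "medium": {
        "contrast": 236.06, "entropy": 11.92,
        "homogeneity": 0.2043, "correlation": 0.8436,
    },
    "intense": {
        "contrast": 307.06, "entropy": 12.16,
        "homogeneity": 0.1717, "correlation": 0.7491,
    },
}

#: Raman G-band (1588 cm⁻¹) relative intensities per toast level —
#: a carbonisation marker (sp² aromatic carbon stretching).
RAMAN_G: dict[str, float] = {"light": 1.14, "medium": 1.09, "intense": 4.32}

# FTIR band intensities are not available as published scalars; the triples
# below are SYNTHETIC placeholders chosen to follow the qualitative trend
# (the O–H band at 3547 cm⁻¹ weakens with toasting as hydroxyl-bearing
# polymers degrade; the C=O band at 1666 cm⁻¹ grows as carbonyls form).
# They are injectable wherever they are consumed.
FTIR_OH_PLACEHOLDER: dict[str, float] = {"light": 1.00, "medium": 0.70, "intense": 0.40}
FTIR_CO_PLACEHOLDER: dict[str, float] = {"light": 0.20, "medium": 0.55, "intense": 0.90}

#: Column order of the toast-level × descriptor feature matrix.
DESCRIPTOR_ORDER: tuple[str, ...] = (
    "ftir_oh",
    "ftir_co",
    "raman_g",
    "contrast",
    "entropy",
    "homogeneity",
    "a1",
    "a2",
    "k1",
    "k2",
    "eci_eq",
)
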