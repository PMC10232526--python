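"""Reference study diets.

Two isocaloric, macronutrient-matched diets differing only in the substrate
they deliver to the colon:

* **MBD** (Microbiome Enhancer Diet): high fiber and resistant starch, large
  food particles, minimally processed.
* **WD** (Western Diet): low fiber and resistant starch, highly processed.

Both provide 50% of kcal as carbohydrate, 34% as fat, and 16% as protein
(the free-living profile of the study sample, which matched the study
diets).  Fiber counts 2 kcal/g and other carbohydrate 4 kcal/g when the
gram amounts are derived from the kcal targets, so total kcal is consistent
with the Atwater factors used throughout.  Profiles scale linearly with
energy intake.
"""

from __future__ import annotations

from .stoichiometry import MacronutrientProfile

__all__ = ["reference_diets", "DIET_PROCESSED", "MACRO_KCAL_FRACTIONS", "FIBER_RS_PER_2000"]

#: fraction of total kcal per macronutrient (CHO/fat/protein)
MACRO_KCAL_FRACTIONS = {"cho": 0.50, "fat": 0.34, "protein": 0.16}

#: grams of fiber (NSP) and resistant starch per 2000 kcal for each diet
FIBER_RS_PER_2000 = {"MBD": (45.0, 30.0), "WD": (15.0, 3.0)}

#: whether a diet counts as "processed" for the upper-GI particle-size penalty
DIET_PROCESSED = {"MBD": False, "WD": True}


def _profile(kcal: float, fiber_g: float, rs_g: float) -> MacronutrientProfile:
    cho_kcal = MACRO_KCAL_FRACTIONS["cho"] * kcal
    fat_g = MACRO_KCAL_FRACTIONS["fat"] * kcal / 9.0
    protein_g = MACRO_KCAL_FRACTIONS["protein"] * kcal / 4.0
    # fiber contributes 2 kcal/g, all other carbohydrate 4 kcal/g
    cho_total_g = fiber_g + (cho_kcal - 2.0 * fiber_g) / 4.0
    return MacronutrientProfile(
        cho_total_g=cho_total_g,
        fat_g=fat_g,
        protein_g=protein_g,
        fiber_nsp_g=fiber_g,
        resistant_starch_g=rs_g,
        kcal_total=kcal,
    )


def reference_diets(kcal: float = 2000.0) -> tuple[MacronutrientProfile, MacronutrientProfile]:
    """Return the (MBD, WD) reference profiles at a given daily energy intake."""
    if kcal <= 0:
        raise ValueError("kcal must be > 0")
    scale = kcal / 2000.0
    mbd_fiber, mbd_rs = FIBER_RS_PER_2000["MBD"]
    wd_fiber, wd_rs = FIBER_RS_PER_2000["WD"]
    mbd = _profile(kcal, mbd_fiber * scale, mbd_rs * scale)
    wd = _profile(kcal, wd_fiber * scale, wd_rs * scale)
    return mbd, wd
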