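"""Score a single product under the FSA-NPS (Nutri-Score) point system.

A fruit yogurt, per 100 g: 450 kJ, 12 g sugars, 2.1 g saturated fat,
60 mg sodium, 10% fruit, 0.2 g fiber, 4.1 g protein.
"""

from nutribasket import NutrientProfile, score_profile, total_fsa_score

yogurt = NutrientProfile(
    energy_kj=450, sugars_g=12.0, satfat_g=2.1, sodium_mg=60,
    fvln_pct=10.0, fiber_g=0.2, protein_g=4.1,
)
pts = score_profile(yogurt)
print("component points:", pts.as_dict())
print("negative total:", pts.negative_total, "| positive total:", pts.positive_total)
print("FSA-NPS score:", total_fsa_score(pts))
# The score lives on -15 (healthiest) .. +40 (least healthy); negative
# points (energy, sugar, saturated fat, sodium) minus counted positive
# points (fruit/veg, fiber, protein).
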