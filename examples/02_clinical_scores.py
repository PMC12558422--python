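"""Score frailty (FTS-5) and nutritional status (CONUT) for two profiles.

FTS-5 sums five 0-10 domains; a total strictly above 25 marks frailty.
CONUT combines graded albumin/lymphocyte/cholesterol subscores (0-12 total)
into malnutrition categories.
"""

from urbanfrail import FTS5Domains, LabPanel, fts5_result, fts_subscale, score_conut

robust = FTS5Domains(nutrition=2, physical_activity=3, nervous_system=1,
                     strength=2, gait_speed=2)
frail = FTS5Domains(nutrition=6, physical_activity=7, nervous_system=5,
                    strength=6, gait_speed=4)

for label, dom in (("robust", robust), ("frail-range", frail)):
    res = fts5_result(dom)
    fts3 = fts_subscale(dom)  # physical_activity + strength + gait_speed
    print(f"{label}: FTS-5 total {res.total:.0f}/50 -> "
          f"{'frail' if res.frail else 'nonfrail'} (FTS-3 subscale {fts3:.0f}/30)")

well = LabPanel(albumin=4.2, lymphocytes=2000, total_cholesterol=200)
poor = LabPanel(albumin=3.1, lymphocytes=1100, total_cholesterol=130)
for label, panel in (("well-nourished", well), ("at-risk", poor)):
    c = score_conut(panel)
    print(f"{label}: CONUT subscores (alb {c.albumin_sub}, lym {c.lymphocyte_sub}, "
          f"chol {c.cholesterol_sub}) -> total {c.total} = {c.category}")
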