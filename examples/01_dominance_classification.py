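"""Classify population records into the three-level dominance coding.

Builds a handful of population records of the kinds found in the
literature — raw contest counts, a summarized percentage, a qualitative
statement, a multi-group study — and shows the strict-dominance rule
(> 90 % of intersexual contests won by one sex, or a report that one sex
always wins) plus the group-level contest statistics.
"""

from phylodom import (
    PopulationObservation,
    aggregate_groups,
    classify_dominance,
    contest_mix_fractions,
    opposite_sex_dyad_fraction,
    percent_won_by_females,
)

records = {
    "counts, females win 91/100": PopulationObservation(
        "Lemur_catta", "berenty", wins_female=91, wins_male=9),
    "counts, exactly 90/100": PopulationObservation(
        "Lemur_catta", "anja", wins_female=90, wins_male=10),
    "counts, males win all": PopulationObservation(
        "Papio_anubis", "gombe", wins_female=0, wins_male=10),
    "qualitative only": PopulationObservation(
        "Loris_tardigradus", "zoo1", qualitative_dominance="male_always"),
    "percentage only (61%)": PopulationObservation(
        "Erythrocebus_patas", "kala", pct_female_won=0.61),
    "two groups pooled (4/10 + 6/10)": aggregate_groups([
        PopulationObservation("Pan_paniscus", "wamba", wins_female=4,
                              wins_male=6),
        PopulationObservation("Pan_paniscus", "wamba", wins_female=6,
                              wins_male=4)]),
}

print(f"{'record':<32} {'% won by females':>17}  category")
for label, obs in records.items():
    try:
        pct = f"{100 * percent_won_by_females(obs):.0f}%"
    except Exception:
        pct = "-"
    print(f"{label:<32} {pct:>17}  {classify_dominance(obs)}")

mm, ff, mf = contest_mix_fractions(10, 10, 20)
print(f"\ncontest mix for (mm=10, ff=10, mf=20): "
      f"{mm:.0%} male-male, {ff:.0%} female-female, {mf:.0%} intersexual")
print(f"opposite-sex dyad fraction for 3 males + 5 females: "
      f"{opposite_sex_dyad_fraction(3, 5):.3f} "
      f"(15 of the 28 possible adult dyads are mixed-sex)")
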