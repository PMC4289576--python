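"""Score a handful of questionnaire records and classify the respondents.

Builds four respondents with engineered answer patterns, derives the 6+6
risk/resource indicators, and prints each respondent's scores and class.
The class shares at the end are percentages of scorable records.
"""

from faindex import QuestionnaireRecord, score_cohort

good = dict(
    weight_loss_5kg="no", changed_walk_1km="no", changed_climb_10steps="no",
    changed_car_bus="no", walk_outside_freq="5-7", falls_12mo="no",
    walk_500m="yes", moderate_activity_freq="1-2", strenuous_activity_freq="1-2",
    work_or_volunteer_7d="yes", fear_falling_limits="no",
)

respondents = [
    QuestionnaireRecord(**good),  # fully robust
    QuestionnaireRecord(**{**good, "weight_loss_5kg": "yes",
                           "changed_walk_1km": "yes", "falls_12mo": "yes"}),
    QuestionnaireRecord(**{**good, "walk_500m": "no",
                           "moderate_activity_freq": "never",
                           "strenuous_activity_freq": "never",
                           "work_or_volunteer_7d": "no"}),
    QuestionnaireRecord(**{**good, "falls_12mo": None}),  # missing answer
]

result = score_cohort(respondents)
cols = ["risk_score", "resource_score", "fa_class", "pooled_class", "scorable"]
print(result.table[cols].to_string())
print()
print("Scorable:", result.n_scorable, "of", result.n_total,
      "(missing answers are excluded, never imputed)")
print()
print("Class shares among scorable records:")
print(result.summary().to_string())
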