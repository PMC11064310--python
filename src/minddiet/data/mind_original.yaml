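# Original MIND scoring table: 15 components (10 brain-healthy including
# olive oil and wine, 5 unhealthy).  Same band conventions as mymindd.yaml.
# The wine component is non-monotone by design (moderate intake scores 1,
# both abstention and heavy intake score 0) and is flagged monotone: false.
name: MIND-original
components:
  - id: whole_grains
    display_name: Whole grains
    polarity: healthy
    kind: frequency
    canonical_unit: per_day
    bands:
      - {points: 0, upper: [1, per_day]}
      # printed "1-2 servings/day" widened to [1/day, 3/day)
      - {points: 0.5, lower: [1, per_day], upper: [3, per_day]}
      - {points: 1, lower: [3, per_day]}
  - id: green_leafy
    display_name: Green leafy vegetables
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: 2, upper_closed: true}
      - {points: 0.5, lower: 2, lower_closed: false, upper: 6}
      # printed "6 servings/week" read as >= 6
      - {points: 1, lower: 6}
  - id: other_vegetables
    display_name: Other vegetables
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: 5}
      - {points: 0.5, lower: 5, upper: 7}
      # printed ">= 1 serving/day" = >= 7/week
      - {points: 1, lower: [1, per_day]}
  - id: berries
    display_name: Berries
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: 1}
      - {points: 0.5, lower: 1, upper: 2}
      - {points: 1, lower: 2}
  - id: olive_oil
    display_name: Olive oil
    polarity: healthy
    kind: categorical
    categories:
      not_primary: 0
      primary: 1
  - id: fish
    display_name: Fish (not fried)
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: [1, per_month]}
      - {points: 0.5, lower: [1, per_month], upper: [1, per_week]}
      - {points: 1, lower: [1, per_week]}
  - id: beans
    display_name: Beans
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: 1}
      - {points: 0.5, lower: 1, upper: 3, upper_closed: true}
      - {points: 1, lower: 3, lower_closed: false}
  - id: nuts
    display_name: Nuts
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: [1, per_month]}
      - {points: 0.5, lower: [1, per_month], upper: 5}
      - {points: 1, lower: 5}
  - id: poultry
    display_name: Poultry (not fried)
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: 1}
      - {points: 0.5, lower: 1, upper: 2}
      - {points: 1, lower: 2}
  - id: wine
    display_name: Wine
    polarity: healthy
    kind: frequency
    canonical_unit: per_day
    monotone: false
    bands:
      # "never" (and trace intake below 1 glass/month) scores 0
      - {points: 0, upper: [1, per_month]}
      - {points: 0.5, lower: [1, per_month], upper: 6, upper_closed: true}
      # "1 glass/day": (6, 7] servings/week
      - {points: 1, lower: 6, lower_closed: false, upper: [1, per_day], upper_closed: true}
      # "> 1 glass/day" scores 0
      - {points: 0, lower: [1, per_day], lower_closed: false}
  - id: red_meat
    display_name: Red meat and products
    polarity: unhealthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 1, upper: 4}
      - {points: 0.5, lower: 4, upper: 7}
      - {points: 0, lower: 7}
  - id: butter_margarine
    display_name: Butter, margarine
    polarity: unhealthy
    kind: frequency
    canonical_unit: per_day
    bands:
      - {points: 1, upper: [1, per_day]}
      - {points: 0.5, lower: [1, per_day], upper: [2, per_day], upper_closed: true}
      - {points: 0, lower: [2, per_day], lower_closed: false}
  - id: cheese
    display_name: Cheese
    polarity: unhealthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 1, upper: 1}
      - {points: 0.5, lower: 1, upper: 7}
      - {points: 0, lower: 7}
  - id: pastries_sweets
    display_name: Pastries and sweets
    polarity: unhealthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 1, upper: 5}
      - {points: 0.5, lower: 5, upper: 7}
      - {points: 0, lower: 7}
  - id: fried_fast_foods
    display_name: Fried/fast foods
    polarity: unhealthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 1, upper: 1}
      - {points: 0.5, lower: 1, upper: 4}
      - {points: 0, lower: 4}
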