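# MY-MINDD scoring table: 11 food-group components (7 brain-healthy, 4
# unhealthy), each scored 0 / 0.5 / 1 by intake frequency band.
#
# Band bounds are either a plain number (servings/week) or a [amount, unit]
# pair normalised to servings/week at load time.  Defaults per band:
#   lower: 0 (closed), upper: infinity (open).
# Printed bands leave small gaps; bands here are widened to half-open
# partitions of [0, inf) so every non-negative intake is scorable.
name: MY-MINDD
components:
  - id: whole_grains
    display_name: Whole grains
    polarity: healthy
    kind: frequency
    canonical_unit: per_day
    bands:
      - {points: 0, upper: [1, per_day]}
      - {points: 0.5, lower: [1, per_day], upper: [3, per_day]}
      - {points: 1, lower: [3, per_day]}
  - id: green_leafy
    display_name: Green leafy vegetables
    polarity: healthy
    kind: frequency
    canonical_unit: per_day
    bands:
      - {points: 0, upper: [0.5, per_day]}
      - {points: 0.5, lower: [0.5, per_day], upper: [1, per_day]}
      - {points: 1, lower: [1, per_day]}
  - id: other_vegetables
    display_name: Other vegetables
    polarity: healthy
    kind: frequency
    canonical_unit: per_day
    bands:
      - {points: 0, upper: [1, per_day]}
      - {points: 0.5, lower: [1, per_day], upper: [3, per_day]}
      - {points: 1, lower: [3, per_day]}
  - id: flavonoid_fruits
    display_name: Flavonoid-rich fruits
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: 1}
      # printed "1 serving/week" widened to [1, 2)
      - {points: 0.5, lower: 1, upper: 2}
      - {points: 1, lower: 2}
  - id: deep_sea_fish
    display_name: Deep-sea fish (not fried)
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: 0.5}
      - {points: 0.5, lower: 0.5, upper: 1}
      - {points: 1, lower: 1}
  - id: legumes_soy
    display_name: Legumes and soy products
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: 1}
      - {points: 0.5, lower: 1, upper: 3}
      - {points: 1, lower: 3}
  - id: poultry
    display_name: Poultry (not fried)
    polarity: healthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 0, upper: 1}
      # printed "1 serving/week" widened to [1, 2)
      - {points: 0.5, lower: 1, upper: 2}
      - {points: 1, lower: 2}
  - id: desserts_kuih
    display_name: Desserts, sweetened kuih and beverages
    polarity: unhealthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 1, upper: 5}
      # printed "5 to 6" widened to [5, 7)
      - {points: 0.5, lower: 5, upper: 7}
      - {points: 0, lower: 7}
  - id: butter_margarine
    display_name: Butter, margarine
    polarity: unhealthy
    kind: frequency
    canonical_unit: per_day   # tablespoons/day, treated dimensionally like servings
    bands:
      - {points: 1, upper: [1, per_day]}
      - {points: 0.5, lower: [1, per_day], upper: [2, per_day], upper_closed: true}
      - {points: 0, lower: [2, per_day], lower_closed: false}
  - id: red_meat
    display_name: Red meat
    polarity: unhealthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 1, upper: 4}
      # printed "4 to 6" widened to [4, 7)
      - {points: 0.5, lower: 4, upper: 7}
      - {points: 0, lower: 7}
  - id: fried_fast_foods
    display_name: Fried/fast foods
    polarity: unhealthy
    kind: frequency
    canonical_unit: per_week
    bands:
      - {points: 1, upper: 1}
      # printed "1 to 3" widened to [1, 4)
      - {points: 0.5, lower: 1, upper: 4}
      - {points: 0, lower: 4}
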