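# Default configuration for CAPKO database construction.
# All losses are fractions in [0, 1); concentrations are mg capsaicinoid
# per 100 g; fractions of product mass are percent.

trim_cuts:
  low: 10.0     # literature values below this are discarded as outliers
  high: 220.0   # and above this

# Five-level red-pepper-powder spiciness scale. Two parameter sets:
# "narrative" carries the level means as first reported (26.2 / 59.1 for
# mild / medium hot); "computation_consistent" carries the set actually
# propagated into every downstream food table (26.6 / 59.0). The latter
# is the default for database construction.
default_scale: computation_consistent
scales:
  narrative:
    - {name: mild, lower: 10.54, upper: 36.81, mean_conc: 26.2}
    - {name: slightly hot, lower: 40.29, upper: 50.04, mean_conc: 45.8}
    - {name: medium hot, lower: 53.99, upper: 68.8, mean_conc: 59.1}
    - {name: very hot, lower: 77.7, upper: 102.3, mean_conc: 86.6}
    - {name: extremely hot, lower: 113.52, upper: 203.8, mean_conc: 153.8}
  computation_consistent:
    - {name: mild, lower: 10.54, upper: 36.81, mean_conc: 26.6}
    - {name: slightly hot, lower: 40.29, upper: 50.04, mean_conc: 45.8}
    - {name: medium hot, lower: 53.99, upper: 68.8, mean_conc: 59.0}
    - {name: very hot, lower: 77.7, upper: 102.3, mean_conc: 86.6}
    - {name: extremely hot, lower: 113.52, upper: 203.8, mean_conc: 153.8}

# dihydrocapsaicin : capsaicin ratios used to impute missing
# dihydrocapsaicin values, per cultivar/study row.
dhc_to_cap_ratio:
  Korean chili pepper red: 0.5
  Cheongyang Chung and Kang: 0.3

salting_water_loss: 0.10   # fresh -> drained weight for salted vegetables

fermentation_loss:         # terminal capsaicinoid loss, per category
  kimchi: 0.20
  red pepper paste: 0.10
  default: 0.0

# Salted seafood declared red-pepper-powder fractions: products other
# than salted pollock roe cluster near 5%, so 5% is assumed for them
# (including items with no label data at all).
salted_seafood_default_pct: 5.0
salted_seafood_default_exceptions:
  - salted pollock roe

# Kimchi types without a standardized recipe inherit the corrected
# fraction of a donor kimchi with mechanically similar vegetables.
kimchi_surrogates:
  cucumber kimchi: cubed Korean radish kimchi
  ponytail radish kimchi: young radish kimchi
  mustard green kimchi: young radish kimchi
  green onion kimchi: young radish kimchi
  rapeseed leaf kimchi: young radish kimchi
  sonchus-leaf crepidiastrum kimchi: young radish kimchi

# Chicken seasoning sauce has no published assay; the sweet hot chili
# sauce mean is reused on similarity of spiciness.
hot_sauce_surrogates:
  chicken seasoning sauce: sweet hot chili sauce

# NAQS napa-cabbage-kimchi spiciness certification thresholds
# (mg capsaicinoid / 100 g kimchi).
naqs_thresholds:
  mild_upper: 0.4    # mild when content < 0.4
  hot_lower: 1.2     # hot when content > 1.2; moderately hot in between

# Published measurement ranges used to validate calculated contents.
validation_ranges:
  napa cabbage kimchi: {lower: 0.2, upper: 1.35}
  red pepper paste: {lower: 2.46, upper: 9.64}

# Food groups present in the source survey but excluded from the
# database because source fractions cannot be generalized.
excluded_foods:
  - seasonings for stew-like dishes
  - spicy snacks
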