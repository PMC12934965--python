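# Example PP3/BP4 calibration tables.
#
# Score intervals per evidence-point tier: `pathogenic` maps points (+1..+4)
# to the minimum qualifying score (score >= threshold); `benign` maps points
# (-1..-4) to the maximum qualifying score (score <= threshold).  Scores in
# the gap between the two regions are indeterminate (0 points).
#
# These values are ILLUSTRATIVE, shaped like published ClinGen-style
# calibrations but not verified transcriptions of them; replace them with
# the thresholds from the primary calibration literature before any real
# use.  BP4-strong (-4) is deliberately absent: many predictors never reach
# that evidence strength.

revel_like:
  higher_is_pathogenic: true
  pathogenic:
    1: 0.644
    2: 0.773
    3: 0.859
    4: 0.932
  benign:
    -1: 0.290
    -2: 0.183
    -3: 0.016

mutpred_like:
  higher_is_pathogenic: true
  pathogenic:
    1: 0.737
    2: 0.829
    3: 0.895
    4: 0.932
  benign:
    -1: 0.391
    -2: 0.197
    -3: 0.031

alphamissense_like:
  higher_is_pathogenic: true
  pathogenic:
    1: 0.787
    2: 0.906
    3: 0.972
    4: 0.990
  benign:
    -1: 0.169
    -2: 0.099
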