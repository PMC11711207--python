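# Standard FFMQ-39 item -> facet assignment with reverse-scored flags.
# Facets: AA (acting with awareness), NJ (non-judging), NR (non-reactivity),
# D (describing), O (observing). Items are 1-based questionnaire positions,
# each rated 1-5; reverse-scored items contribute (6 - response).
items:
  1:  {facet: O,  reverse: false}
  2:  {facet: D,  reverse: false}
  3:  {facet: NJ, reverse: true}
  4:  {facet: NR, reverse: false}
  5:  {facet: AA, reverse: true}
  6:  {facet: O,  reverse: false}
  7:  {facet: D,  reverse: false}
  8:  {facet: AA, reverse: true}
  9:  {facet: NR, reverse: false}
  10: {facet: NJ, reverse: true}
  11: {facet: O,  reverse: false}
  12: {facet: D,  reverse: true}
  13: {facet: AA, reverse: true}
  14: {facet: NJ, reverse: true}
  15: {facet: O,  reverse: false}
  16: {facet: D,  reverse: true}
  17: {facet: NJ, reverse: true}
  18: {facet: AA, reverse: true}
  19: {facet: NR, reverse: false}
  20: {facet: O,  reverse: false}
  21: {facet: NR, reverse: false}
  22: {facet: D,  reverse: true}
  23: {facet: AA, reverse: true}
  24: {facet: NR, reverse: false}
  25: {facet: NJ, reverse: true}
  26: {facet: O,  reverse: false}
  27: {facet: D,  reverse: false}
  28: {facet: AA, reverse: true}
  29: {facet: NR, reverse: false}
  30: {facet: NJ, reverse: true}
  31: {facet: O,  reverse: false}
  32: {facet: D,  reverse: false}
  33: {facet: NR, reverse: false}
  34: {facet: AA, reverse: true}
  35: {facet: NJ, reverse: true}
  36: {facet: O,  reverse: false}
  37: {facet: D,  reverse: false}
  38: {facet: AA, reverse: true}
  39: {facet: NJ, reverse: true}
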