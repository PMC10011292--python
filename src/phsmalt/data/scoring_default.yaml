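# Illustrative SYNTHETIC scoring configuration for adjunct / all-malt end-use
# ranking and breeding-target classification.  Band boundaries and point
# values are plausible for North American 2-row spring malting barley but are
# invented for tests and demonstrations; they are not any lab's published
# score tables.  Bands are half-open [lo, hi); values outside every band
# score 0 points.
traits:
  AA:
    adjunct:
      bands:
        - {lo: 70.0, points: 3}
        - {lo: 60.0, hi: 70.0, points: 2}
        - {lo: 50.0, hi: 60.0, points: 1}
      target: {lo: 60.0}
    all_malt:
      bands:
        - {lo: 40.0, hi: 60.0, points: 3}
        - {lo: 60.0, hi: 70.0, points: 2}
        - {lo: 30.0, hi: 40.0, points: 1}
      target: {lo: 40.0, hi: 70.0}
  DP:
    adjunct:
      bands:
        - {lo: 150.0, points: 3}
        - {lo: 130.0, hi: 150.0, points: 2}
        - {lo: 110.0, hi: 130.0, points: 1}
      target: {lo: 140.0}
    all_malt:
      bands:
        - {lo: 100.0, hi: 140.0, points: 3}
        - {lo: 140.0, hi: 160.0, points: 2}
        - {lo: 90.0, hi: 100.0, points: 1}
      target: {lo: 100.0, hi: 160.0}
  FAN:
    adjunct:
      bands:
        - {lo: 210.0, points: 3}
        - {lo: 190.0, hi: 210.0, points: 2}
        - {lo: 170.0, hi: 190.0, points: 1}
      target: {lo: 200.0}
    all_malt:
      bands:
        - {lo: 140.0, hi: 190.0, points: 3}
        - {lo: 190.0, hi: 210.0, points: 2}
        - {lo: 120.0, hi: 140.0, points: 1}
      target: {lo: 140.0, hi: 210.0}
  ME:
    adjunct:
      bands:
        - {lo: 80.0, points: 3}
        - {lo: 79.0, hi: 80.0, points: 2}
        - {lo: 78.0, hi: 79.0, points: 1}
      target: {lo: 79.0}
    all_malt:
      bands:
        - {lo: 80.5, points: 3}
        - {lo: 79.5, hi: 80.5, points: 2}
        - {lo: 78.5, hi: 79.5, points: 1}
      target: {lo: 79.0}
  SP:
    adjunct:
      bands:
        - {lo: 5.3, hi: 6.2, points: 3}
        - {lo: 5.0, hi: 5.3, points: 2}
        - {lo: 6.2, hi: 6.5, points: 1}
      target: {lo: 5.2, hi: 6.3}
    all_malt:
      bands:
        - {lo: 4.8, hi: 5.6, points: 3}
        - {lo: 5.6, hi: 6.0, points: 2}
        - {lo: 4.4, hi: 4.8, points: 1}
      target: {lo: 4.6, hi: 5.9}
  ST:
    adjunct:
      bands:
        - {lo: 44.0, hi: 55.0, points: 3}
        - {lo: 40.0, hi: 44.0, points: 2}
        - {lo: 55.0, hi: 60.0, points: 1}
      target: {lo: 42.0, hi: 56.0}
    all_malt:
      bands:
        - {lo: 38.0, hi: 47.0, points: 3}
        - {lo: 47.0, hi: 52.0, points: 2}
        - {lo: 34.0, hi: 38.0, points: 1}
      target: {lo: 36.0, hi: 50.0}
  BG:
    adjunct:
      bands:
        - {lo: 0.0, hi: 120.0, points: 3}
        - {lo: 120.0, hi: 200.0, points: 2}
        - {lo: 200.0, hi: 280.0, points: 1}
      target: {hi: 220.0}
    all_malt:
      bands:
        - {lo: 0.0, hi: 100.0, points: 3}
        - {lo: 100.0, hi: 180.0, points: 2}
        - {lo: 180.0, hi: 260.0, points: 1}
      target: {hi: 200.0}
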