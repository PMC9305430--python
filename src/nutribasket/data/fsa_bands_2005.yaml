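# 2005 UK FSA nutrient-profiling band table, per 100 g of product.
# Band membership is lower-exclusive / upper-inclusive: a value v earns the
# points of the first band with v <= upper_bound; `null` marks the open top
# band. Negative components score 0..10, positive components 0..5.
# Fiber bands are the AOAC variant; swap in the NSP variant
# (0.7/1.4/2.1/2.8/3.5) by editing this file or passing a custom table.
version: fsa-2005-aoac
negative:
  energy_kj:
    - {upper_bound: 335, points: 0}
    - {upper_bound: 670, points: 1}
    - {upper_bound: 1005, points: 2}
    - {upper_bound: 1340, points: 3}
    - {upper_bound: 1675, points: 4}
    - {upper_bound: 2010, points: 5}
    - {upper_bound: 2345, points: 6}
    - {upper_bound: 2680, points: 7}
    - {upper_bound: 3015, points: 8}
    - {upper_bound: 3350, points: 9}
    - {upper_bound: null, points: 10}
  sugars_g:
    - {upper_bound: 4.5, points: 0}
    - {upper_bound: 9.0, points: 1}
    - {upper_bound: 13.5, points: 2}
    - {upper_bound: 18.0, points: 3}
    - {upper_bound: 22.5, points: 4}
    - {upper_bound: 27.0, points: 5}
    - {upper_bound: 31.0, points: 6}
    - {upper_bound: 36.0, points: 7}
    - {upper_bound: 40.0, points: 8}
    - {upper_bound: 45.0, points: 9}
    - {upper_bound: null, points: 10}
  satfat_g:
    - {upper_bound: 1.0, points: 0}
    - {upper_bound: 2.0, points: 1}
    - {upper_bound: 3.0, points: 2}
    - {upper_bound: 4.0, points: 3}
    - {upper_bound: 5.0, points: 4}
    - {upper_bound: 6.0, points: 5}
    - {upper_bound: 7.0, points: 6}
    - {upper_bound: 8.0, points: 7}
    - {upper_bound: 9.0, points: 8}
    - {upper_bound: 10.0, points: 9}
    - {upper_bound: null, points: 10}
  sodium_mg:
    - {upper_bound: 90, points: 0}
    - {upper_bound: 180, points: 1}
    - {upper_bound: 270, points: 2}
    - {upper_bound: 360, points: 3}
    - {upper_bound: 450, points: 4}
    - {upper_bound: 540, points: 5}
    - {upper_bound: 630, points: 6}
    - {upper_bound: 720, points: 7}
    - {upper_bound: 810, points: 8}
    - {upper_bound: 900, points: 9}
    - {upper_bound: null, points: 10}
positive:
  fvln_pct:
    - {upper_bound: 40.0, points: 0}
    - {upper_bound: 60.0, points: 1}
    - {upper_bound: 80.0, points: 2}
    - {upper_bound: null, points: 5}
  fiber_g:
    - {upper_bound: 0.9, points: 0}
    - {upper_bound: 1.9, points: 1}
    - {upper_bound: 2.8, points: 2}
    - {upper_bound: 3.7, points: 3}
    - {upper_bound: 4.7, points: 4}
    - {upper_bound: null, points: 5}
  protein_g:
    - {upper_bound: 1.6, points: 0}
    - {upper_bound: 3.2, points: 1}
    - {upper_bound: 4.8, points: 2}
    - {upper_bound: 6.4, points: 3}
    - {upper_bound: 8.0, points: 4}
    - {upper_bound: null, points: 5}
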