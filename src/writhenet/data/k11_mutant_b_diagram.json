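{
 "knot": "K11n42",
 "plat_word": [
  4,
  4,
  -1,
  4,
  -1,
  -2,
  3,
  -2,
  3,
  4,
  4,
  -2,
  -1,
  -2,
  -1,
  2
 ],
 "n_crossings": 11,
 "events": [
  [
   0,
   false
  ],
  [
   1,
   true
  ],
  [
   2,
   false
  ],
  [
   3,
   false
  ],
  [
   4,
   true
  ],
  [
   5,
   false
  ],
  [
   6,
   true
  ],
  [
   7,
   false
  ],
  [
   3,
   true
  ],
  [
   8,
   false
  ],
  [
   5,
   true
  ],
  [
   6,
   false
  ],
  [
   9,
   false
  ],
  [
   10,
   true
  ],
  [
   8,
   true
  ],
  [
   4,
   false
  ],
  [
   7,
   true
  ],
  [
   0,
   true
  ],
  [
   1,
   false
  ],
  [
   2,
   true
  ],
  [
   10,
   false
  ],
  [
   9,
   true
  ]
 ],
 "signs": [
  1,
  1,
  1,
  1,
  1,
  -1,
  -1,
  1,
  -1,
  -1,
  -1
 ],
 "psl27_homomorphisms": 1512,
 "a5_homomorphisms": 180
}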