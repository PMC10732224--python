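{
 "knot": "K11n34",
 "plat_word": [
  -1,
  -2,
  3,
  -2,
  4,
  -3,
  -5,
  4,
  1,
  -3,
  2,
  2,
  4
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
   true
  ],
  [
   4,
   false
  ],
  [
   0,
   true
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
   7,
   true
  ],
  [
   8,
   false
  ],
  [
   9,
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
   10,
   false
  ],
  [
   8,
   true
  ],
  [
   2,
   true
  ],
  [
   3,
   false
  ],
  [
   7,
   false
  ],
  [
   10,
   true
  ],
  [
   9,
   false
  ],
  [
   1,
   false
  ],
  [
   4,
   true
  ]
 ],
 "signs": [
  1,
  1,
  -1,
  -1,
  1,
  -1,
  -1,
  1,
  1,
  -1,
  -1
 ],
 "psl27_homomorphisms": 1176,
 "a5_homomorphisms": 180
}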