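{
  "comment": "Simplified Turner-style nearest-neighbour free-energy parameters (kcal/mol, 37 C). Stacks are indexed stack[outer][inner] where the outer pair (i,j) closes the inner pair (i+1,j-1); pair order is AU, UA, GC, CG, GU, UG. Loop tables are indexed by loop size starting at the minimum size for that loop type; larger loops extrapolate as E(max) + 1.75 * RT * ln(n/max).",
  "pair_order": ["AU", "UA", "GC", "CG", "GU", "UG"],
  "stack": [
    [-0.9, -1.1, -2.1, -2.2, -0.6, -1.4],
    [-1.3, -0.9, -2.4, -2.1, -1.0, -1.3],
    [-2.4, -2.2, -3.3, -3.4, -1.5, -2.5],
    [-2.1, -2.1, -2.4, -3.3, -1.4, -2.1],
    [-1.3, -1.4, -2.1, -2.5, -0.5, -0.6],
    [-1.0, -0.6, -1.4, -1.5, -0.3, -0.5]
  ],
  "hairpin_min": 3,
  "hairpin": [5.4, 5.6, 5.7, 5.4, 6.0, 5.5, 6.4],
  "bulge": [3.8, 2.8, 3.2, 3.6, 4.0, 4.4],
  "internal": [1.5, 1.6, 1.7, 2.0, 2.0, 2.2, 2.3],
  "internal_asymmetry": 0.5,
  "internal_asymmetry_max": 3.0,
  "multiloop_closing": 3.4,
  "multiloop_branch": 0.4,
  "multiloop_unpaired": 0.0,
  "max_interior_size": 30,
  "rt": 0.616
}
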