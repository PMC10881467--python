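{
 "background_suitability": {
  "background_bins": {
   "0-5kb": 67,
   "5-50kb": 133,
   "50-500kb": 0,
   ">500kb": 0
  },
  "n_background": 200,
  "n_ucne": 5,
  "p": 0.6524885091705565,
  "statistic": 0.2027771227113204,
  "ucne_bins": {
   "0-5kb": 0,
   "5-50kb": 5,
   "50-500kb": 0,
   ">500kb": 0
  }
 },
 "concordant_fraction": 0.3333333333333333,
 "config_hash": "3ca2d3d01c207230",
 "constraint": {
  "H": 1757.4322143548693,
  "group_medians": [
   -0.9962590566194126,
   -0.5501679646076959,
   0.0030732273424892713
  ],
  "group_sizes": [
   1600,
   2000,
   70000
  ],
  "p": 0.0,
  "pairwise": [
   {
    "i": 0,
    "j": 1,
    "p_adjusted": 2.6124912474373786e-28,
    "z": -11.132574870719953
   },
   {
    "i": 0,
    "j": 2,
    "p_adjusted": 6.606577261618561e-276,
    "z": -35.52259227810221
   },
   {
    "i": 1,
    "j": 2,
    "p_adjusted": 5.538960787177408e-118,
    "z": -23.139690865846728
   }
  ]
 },
 "n_active_enhancer": 1,
 "n_any_activating_mark": 2,
 "n_any_assessed_mark": 2,
 "n_disease_genes": 1,
 "n_edges": 5,
 "n_expressed_genes": 2,
 "n_high_confidence": 1,
 "n_marked": 2,
 "n_open": 3,
 "n_rare_variants": 3,
 "n_sustained_adult": 1,
 "n_tad_consistent_genes": 2,
 "n_target_genes": 3,
 "n_ucne_hits": 3,
 "n_ucnes": 5,
 "search_space": {
  "genes": 1,
  "ucnes": 1,
  "variants": 1,
  "variants_in_unsolved_cases": 1
 },
 "seed": 0,
 "spectrum": {
  "density_ratio": {
   "common": NaN,
   "low_frequency": NaN,
   "rare": NaN,
   "ultrarare": 131.25,
   "very_rare": NaN
  },
  "density_ratio_se": {
   "common": NaN,
   "low_frequency": NaN,
   "rare": NaN,
   "ultrarare": 151.55444566227675,
   "very_rare": NaN
  },
  "proportion_ratio": {
   "common": NaN,
   "low_frequency": NaN,
   "rare": NaN,
   "ultrarare": 0.6,
   "very_rare": NaN
  }
 },
 "tad_consistent_fraction": 1.0,
 "variant_bin_counts": {
  "common": 1,
  "low_frequency": 0,
  "rare": 1,
  "ultrarare": 3,
  "very_rare": 0
 },
 "version": "0.1.0",
 "vista": {
  "all_ucnes": {
   "n_overlapped": 2,
   "n_positive": 1,
   "positive_proportion": 0.5,
   "tissue_mention_fractions": {
    "eye": 1.0
   }
  },
  "open_ucnes": {
   "n_overlapped": 2,
   "n_positive": 1,
   "positive_proportion": 0.5,
   "tissue_mention_fractions": {
    "eye": 1.0
   }
  }
 }
}
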