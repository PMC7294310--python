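{
  "name": "Precision Plus Protein Unstained Standards",
  "description": "Ten recombinant protein bands; loads are the manufacturer-stated nanograms per band for a 10 ul lane and scale linearly with loaded volume. Bands without a stated load have load_ng_per_10ul null and must not be used for mass calibration.",
  "bands": [
    {"mw_kda": 250, "load_ng_per_10ul": null, "is_reference": false},
    {"mw_kda": 150, "load_ng_per_10ul": null, "is_reference": false},
    {"mw_kda": 100, "load_ng_per_10ul": 150, "is_reference": false},
    {"mw_kda": 75,  "load_ng_per_10ul": null, "is_reference": true},
    {"mw_kda": 50,  "load_ng_per_10ul": 750, "is_reference": true},
    {"mw_kda": 37,  "load_ng_per_10ul": null, "is_reference": false},
    {"mw_kda": 25,  "load_ng_per_10ul": null, "is_reference": true},
    {"mw_kda": 20,  "load_ng_per_10ul": 150, "is_reference": false},
    {"mw_kda": 15,  "load_ng_per_10ul": null, "is_reference": false},
    {"mw_kda": 10,  "load_ng_per_10ul": null, "is_reference": false}
  ]
}
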