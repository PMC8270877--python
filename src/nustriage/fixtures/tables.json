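{
  "comment": "Printed per-class counts of the source study's histology table (table1) and per-score FNA/cytology table (table2). 'expected' = nodules whose class+size indicated FNA; 'observed' = FNA actually performed; spared counts are reproduced as printed ('printed_spared') and are internally inconsistent in two flagged cells - the expansion recomputes spared as observed minus expected componentwise.",
  "table1_histology": {
    "total": 355,
    "counts": {
      "papillary_classic": 166,
      "follicular_variant_papillary": 97,
      "medullary": 12,
      "other_well_differentiated": 70,
      "insular": 3,
      "other_poorly_differentiated": 5,
      "metastasis_other_cancer": 2
    },
    "printed_percent": {
      "papillary_classic": 46.8,
      "follicular_variant_papillary": 27.3,
      "medullary": 3.4,
      "other_well_differentiated": 19.8,
      "insular": 0.8,
      "other_poorly_differentiated": 1.4,
      "metastasis_other_cancer": 0.5
    }
  },
  "table2": {
    "KTIRADS": {
      "classes": {
        "2": {"expected": {"neg": 227, "pos": 7}, "observed": {"neg": 348, "pos": 17}, "printed_spared": {"neg": 121, "pos": 10, "total": 131}},
        "3": {"expected": {"neg": 2102, "pos": 191}, "observed": {"neg": 2607, "pos": 220}, "printed_spared": {"neg": 505, "pos": 29, "total": 534}},
        "4": {"expected": {"neg": 2381, "pos": 323}, "observed": {"neg": 2381, "pos": 323}, "printed_spared": {"neg": 0, "pos": 0, "total": 0}},
        "5": {"expected": {"neg": 429, "pos": 149}, "observed": {"neg": 429, "pos": 149}, "printed_spared": {"neg": 0, "pos": 0, "total": 0}}
      },
      "printed_totals": {"expected": 5809, "observed": 6474, "spared": 665}
    },
    "ATA": {
      "classes": {
        "benign": {"expected": {"neg": 0, "pos": 0}, "observed": {"neg": 53, "pos": 0}, "printed_spared": {"neg": null, "pos": null, "total": null}},
        "very_low": {"expected": {"neg": 9, "pos": 0}, "observed": {"neg": 12, "pos": 0}, "printed_spared": {"neg": 3, "pos": 0, "total": 3}},
        "low": {"expected": {"neg": 2681, "pos": 225}, "observed": {"neg": 3319, "pos": 266}, "printed_spared": {"neg": 638, "pos": 41, "total": 679}},
        "intermediate": {"expected": {"neg": 1135, "pos": 146}, "observed": {"neg": 1135, "pos": 146}, "printed_spared": {"neg": 0, "pos": 0, "total": 0}},
        "high": {"expected": {"neg": 851, "pos": 234}, "observed": {"neg": 851, "pos": 234}, "printed_spared": {"neg": 0, "pos": 0, "total": 0}}
      },
      "printed_totals": {"expected": 5281, "observed": 6016, "spared": 682},
      "unclassifiable": {"n": 458, "printed_positive_rate_percent": 13.8, "n_positive_reconstructed": 63}
    },
    "AACE": {
      "classes": {
        "low": {"expected": {"neg": 828, "pos": 60}, "observed": {"neg": 1481, "pos": 103}, "printed_spared": {"neg": 653, "pos": 43, "total": 696}},
        "intermediate": {"expected": {"neg": 1405, "pos": 145}, "observed": {"neg": 3016, "pos": 306}, "printed_spared": {"neg": 1611, "pos": 161, "total": 1772}},
        "high": {"expected": {"neg": 1268, "pos": 300}, "observed": {"neg": 1268, "pos": 300}, "printed_spared": {"neg": 0, "pos": 0, "total": 0}}
      },
      "printed_totals": {"expected": 4006, "observed": 6474, "spared": 2468}
    },
    "EUTIRADS": {
      "classes": {
        "2": {"expected": {"neg": 8, "pos": 0}, "observed": {"neg": 57, "pos": 0}, "printed_spared": {"neg": 8, "pos": 0, "total": 49}},
        "3": {"expected": {"neg": 1054, "pos": 94}, "observed": {"neg": 1760, "pos": 161}, "printed_spared": {"neg": 706, "pos": 67, "total": 773}},
        "4": {"expected": {"neg": 1991, "pos": 179}, "observed": {"neg": 2680, "pos": 248}, "printed_spared": {"neg": 689, "pos": 69, "total": 758}},
        "5": {"expected": {"neg": 1194, "pos": 272}, "observed": {"neg": 1268, "pos": 300}, "printed_spared": {"neg": 74, "pos": 28, "total": 102}}
      },
      "printed_totals": {"expected": 4792, "observed": 6474, "spared": 1682}
    },
    "ACRTIRADS": {
      "classes": {
        "TR1": {"expected": {"neg": 8, "pos": 0}, "observed": {"neg": 19, "pos": 0}, "printed_spared": {"neg": 11, "pos": 0, "total": 11}},
        "TR2": {"expected": {"neg": 18, "pos": 0}, "observed": {"neg": 226, "pos": 3}, "printed_spared": {"neg": 208, "pos": 3, "total": 211}},
        "TR3": {"expected": {"neg": 166, "pos": 14}, "observed": {"neg": 571, "pos": 34}, "printed_spared": {"neg": 405, "pos": 20, "total": 425}},
        "TR4": {"expected": {"neg": 2472, "pos": 245}, "observed": {"neg": 3093, "pos": 301}, "printed_spared": {"neg": 621, "pos": 56, "total": 667}},
        "TR5": {"expected": {"neg": 1856, "pos": 371}, "observed": {"neg": 1856, "pos": 371}, "printed_spared": {"neg": 0, "pos": 0, "total": 0}}
      },
      "printed_totals": {"expected": 5150, "observed": 6474, "spared": 1324}
    }
  },
  "flags": [
    "EUTIRADS class 2 spared row prints negative count 8 with total 49; observed minus expected gives 49 negatives, consistent with the printed system total 1682.",
    "ACRTIRADS TR4 spared row prints total 667 while its own printed components (621+56) and observed minus expected both give 677; the printed per-class spared entries sum to 1314 while the printed system total is 1324, which matches observed minus expected.",
    "Never-FNA classes (EUTIRADS 2, ACRTIRADS TR1-TR2) carry nonzero printed expected-FNA counts (8, 8, 18) reflecting observed practice rather than the class thresholds.",
    "ATA unclassifiable positive count 63 is reconstructed from the printed rate 13.8% of 458.",
    "ACRTIRADS TR5 positive count prints (193), inconsistent with its own row (1856+193 != 2227; 193/2227 != 16.7%); 371 is used, which reproduces the printed percentages, the printed row and system totals, and the 709 positive-cytology nodules every other system's observed column sums to."
  ]
}
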