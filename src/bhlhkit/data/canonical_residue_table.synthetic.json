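{
  "source": "synthetic reconstruction from the plant bHLH consensus; the historically cited core-11/defined-19 residue identities are not published in machine-readable form, so this default is a package-authored stand-in and mismatch cutoffs based on it are reported, never enforced, by default",
  "core11": {
    "5": "HKR",
    "9": "E",
    "10": "R",
    "12": "R",
    "13": "R",
    "16": "ILVM",
    "20": "LIV",
    "23": "L",
    "26": "VIL",
    "45": "ILV",
    "55": "L"
  },
  "defined19": {
    "4": "RKN",
    "5": "HKR",
    "9": "E",
    "10": "R",
    "12": "R",
    "13": "R",
    "16": "ILVM",
    "17": "PAS",
    "20": "LIV",
    "23": "L",
    "24": "ED",
    "26": "VIL",
    "27": "KR",
    "43": "KR",
    "45": "ILV",
    "48": "AST",
    "52": "ILV",
    "54": "YFW",
    "55": "L"
  }
}
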