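{
  "description": "Additive QTL allele-effect model for the seven fruit-model parameters in a Prunus davidiana (D) x P. persica (S) BC2 progeny. Allele coding: 0 = wild D allele, 1 = S allele; intercepts describe the all-D genotype. 31 loci, 37 effect terms, 5 pleiotropic loci.",
  "parameters": {
    "A": {
      "intercept": 8.29138,
      "effects": {"3": 2.66318, "7": -4.17002, "12": 2.55744, "20": 2.51455, "23": 3.07437, "26": 3.55207}
    },
    "B": {
      "intercept": 1.17567,
      "effects": {"9": -0.25238, "27": -0.20475}
    },
    "RGRini": {
      "intercept": 0.00172,
      "effects": {"1": 0.00059, "14": 0.00038, "17": 0.00066, "22": 0.00119, "25": -0.00041, "31": 0.00079}
    },
    "P3": {
      "intercept": 2695.74,
      "effects": {"14": -227.64, "18": -168.95, "22": -260.25, "25": 129.0, "30": -278.73}
    },
    "kstone": {
      "intercept": 0.19725,
      "effects": {"4": -0.03115, "8": -0.02533, "11": -0.0174, "13": -0.02218, "16": -0.02466, "28": -0.00724, "31": -0.01467}
    },
    "Wstone": {
      "intercept": 3.86701,
      "effects": {"2": 1.33592, "6": 0.92848, "14": 1.83601, "19": -0.22232, "24": -2.02367, "29": 1.33883}
    },
    "SLA": {
      "intercept": 0.02103,
      "effects": {"5": -0.00077, "10": -0.00158, "15": -0.00133, "21": -0.00061, "26": -0.00081}
    }
  },
  "inseparable_pairs": [
    [4, 5], [6, 7], [7, 8], [10, 11], [13, 14], [14, 15], [16, 17],
    [17, 18], [18, 19], [21, 22], [23, 24], [24, 25], [25, 26], [28, 29]
  ],
  "epsilon": 1e-9
}
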