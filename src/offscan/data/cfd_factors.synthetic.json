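{
 "mismatch": {
  "10:A:C": 0.3941,
  "10:A:G": 0.6103,
  "10:A:T": 0.4105,
  "10:C:A": 0.4187,
  "10:C:G": 0.4269,
  "10:C:T": 0.6021,
  "10:G:A": 0.6103,
  "10:G:C": 0.4105,
  "10:G:T": 0.4187,
  "10:T:A": 0.4269,
  "10:T:C": 0.6021,
  "10:T:G": 0.4023,
  "11:A:C": 0.3619,
  "11:A:G": 0.5604,
  "11:A:T": 0.377,
  "11:C:A": 0.3845,
  "11:C:G": 0.3921,
  "11:C:T": 0.5529,
  "11:G:A": 0.5604,
  "11:G:C": 0.377,
  "11:G:T": 0.3845,
  "11:T:A": 0.3921,
  "11:T:C": 0.5529,
  "11:T:G": 0.3694,
  "12:A:C": 0.3297,
  "12:A:G": 0.5106,
  "12:A:T": 0.3434,
  "12:C:A": 0.3503,
  "12:C:G": 0.3572,
  "12:C:T": 0.5037,
  "12:G:A": 0.5106,
  "12:G:C": 0.3434,
  "12:G:T": 0.3503,
  "12:T:A": 0.3572,
  "12:T:C": 0.5037,
  "12:T:G": 0.3366,
  "13:A:C": 0.2975,
  "13:A:G": 0.4607,
  "13:A:T": 0.3099,
  "13:C:A": 0.3161,
  "13:C:G": 0.3223,
  "13:C:T": 0.4545,
  "13:G:A": 0.4607,
  "13:G:C": 0.3099,
  "13:G:T": 0.3161,
  "13:T:A": 0.3223,
  "13:T:C": 0.4545,
  "13:T:G": 0.3037,
  "14:A:C": 0.2653,
  "14:A:G": 0.4108,
  "14:A:T": 0.2763,
  "14:C:A": 0.2818,
  "14:C:G": 0.2874,
  "14:C:T": 0.4053,
  "14:G:A": 0.4108,
  "14:G:C": 0.2763,
  "14:G:T": 0.2818,
  "14:T:A": 0.2874,
  "14:T:C": 0.4053,
  "14:T:G": 0.2708,
  "15:A:C": 0.2331,
  "15:A:G": 0.3609,
  "15:A:T": 0.2428,
  "15:C:A": 0.2476,
  "15:C:G": 0.2525,
  "15:C:T": 0.3561,
  "15:G:A": 0.3609,
  "15:G:C": 0.2428,
  "15:G:T": 0.2476,
  "15:T:A": 0.2525,
  "15:T:C": 0.3561,
  "15:T:G": 0.2379,
  "16:A:C": 0.2008,
  "16:A:G": 0.311,
  "16:A:T": 0.2092,
  "16:C:A": 0.2134,
  "16:C:G": 0.2176,
  "16:C:T": 0.3068,
  "16:G:A": 0.311,
  "16:G:C": 0.2092,
  "16:G:T": 0.2134,
  "16:T:A": 0.2176,
  "16:T:C": 0.3068,
  "16:T:G": 0.205,
  "17:A:C": 0.1686,
  "17:A:G": 0.2611,
  "17:A:T": 0.1757,
  "17:C:A": 0.1792,
  "17:C:G": 0.1827,
  "17:C:T": 0.2576,
  "17:G:A": 0.2611,
  "17:G:C": 0.1757,
  "17:G:T": 0.1792,
  "17:T:A": 0.1827,
  "17:T:C": 0.2576,
  "17:T:G": 0.1721,
  "18:A:C": 0.1364,
  "18:A:G": 0.2113,
  "18:A:T": 0.1421,
  "18:C:A": 0.1449,
  "18:C:G": 0.1478,
  "18:C:T": 0.2084,
  "18:G:A": 0.2113,
  "18:G:C": 0.1421,
  "18:G:T": 0.1449,
  "18:T:A": 0.1478,
  "18:T:C": 0.2084,
  "18:T:G": 0.1393,
  "19:A:C": 0.1042,
  "19:A:G": 0.1614,
  "19:A:T": 0.1086,
  "19:C:A": 0.1107,
  "19:C:G": 0.1129,
  "19:C:T": 0.1592,
  "19:G:A": 0.1614,
  "19:G:C": 0.1086,
  "19:G:T": 0.1107,
  "19:T:A": 0.1129,
  "19:T:C": 0.1592,
  "19:T:G": 0.1064,
  "1:A:C": 0.684,
  "1:A:G": 1.0,
  "1:A:T": 0.7125,
  "1:C:A": 0.7268,
  "1:C:G": 0.741,
  "1:C:T": 1.0,
  "1:G:A": 1.0,
  "1:G:C": 0.7125,
  "1:G:T": 0.7268,
  "1:T:A": 0.741,
  "1:T:C": 1.0,
  "1:T:G": 0.6982,
  "20:A:C": 0.072,
  "20:A:G": 0.1115,
  "20:A:T": 0.075,
  "20:C:A": 0.0765,
  "20:C:G": 0.078,
  "20:C:T": 0.11,
  "20:G:A": 0.1115,
  "20:G:C": 0.075,
  "20:G:T": 0.0765,
  "20:T:A": 0.078,
  "20:T:C": 0.11,
  "20:T:G": 0.0735,
  "2:A:C": 0.6518,
  "2:A:G": 1.0,
  "2:A:T": 0.6789,
  "2:C:A": 0.6925,
  "2:C:G": 0.7061,
  "2:C:T": 0.9958,
  "2:G:A": 1.0,
  "2:G:C": 0.6789,
  "2:G:T": 0.6925,
  "2:T:A": 0.7061,
  "2:T:C": 0.9958,
  "2:T:G": 0.6654,
  "3:A:C": 0.6196,
  "3:A:G": 0.9595,
  "3:A:T": 0.6454,
  "3:C:A": 0.6583,
  "3:C:G": 0.6712,
  "3:C:T": 0.9466,
  "3:G:A": 0.9595,
  "3:G:C": 0.6454,
  "3:G:T": 0.6583,
  "3:T:A": 0.6712,
  "3:T:C": 0.9466,
  "3:T:G": 0.6325,
  "4:A:C": 0.5874,
  "4:A:G": 0.9096,
  "4:A:T": 0.6118,
  "4:C:A": 0.6241,
  "4:C:G": 0.6363,
  "4:C:T": 0.8974,
  "4:G:A": 0.9096,
  "4:G:C": 0.6118,
  "4:G:T": 0.6241,
  "4:T:A": 0.6363,
  "4:T:C": 0.8974,
  "4:T:G": 0.5996,
  "5:A:C": 0.5552,
  "5:A:G": 0.8597,
  "5:A:T": 0.5783,
  "5:C:A": 0.5899,
  "5:C:G": 0.6014,
  "5:C:T": 0.8482,
  "5:G:A": 0.8597,
  "5:G:C": 0.5783,
  "5:G:T": 0.5899,
  "5:T:A": 0.6014,
  "5:T:C": 0.8482,
  "5:T:G": 0.5667,
  "6:A:C": 0.5229,
  "6:A:G": 0.8098,
  "6:A:T": 0.5447,
  "6:C:A": 0.5556,
  "6:C:G": 0.5665,
  "6:C:T": 0.7989,
  "6:G:A": 0.8098,
  "6:G:C": 0.5447,
  "6:G:T": 0.5556,
  "6:T:A": 0.5665,
  "6:T:C": 0.7989,
  "6:T:G": 0.5338,
  "7:A:C": 0.4907,
  "7:A:G": 0.76,
  "7:A:T": 0.5112,
  "7:C:A": 0.5214,
  "7:C:G": 0.5316,
  "7:C:T": 0.7497,
  "7:G:A": 0.76,
  "7:G:C": 0.5112,
  "7:G:T": 0.5214,
  "7:T:A": 0.5316,
  "7:T:C": 0.7497,
  "7:T:G": 0.501,
  "8:A:C": 0.4585,
  "8:A:G": 0.7101,
  "8:A:T": 0.4776,
  "8:C:A": 0.4872,
  "8:C:G": 0.4967,
  "8:C:T": 0.7005,
  "8:G:A": 0.7101,
  "8:G:C": 0.4776,
  "8:G:T": 0.4872,
  "8:T:A": 0.4967,
  "8:T:C": 0.7005,
  "8:T:G": 0.4681,
  "9:A:C": 0.4263,
  "9:A:G": 0.6602,
  "9:A:T": 0.4441,
  "9:C:A": 0.453,
  "9:C:G": 0.4618,
  "9:C:T": 0.6513,
  "9:G:A": 0.6602,
  "9:G:C": 0.4441,
  "9:G:T": 0.453,
  "9:T:A": 0.4618,
  "9:T:C": 0.6513,
  "9:T:G": 0.4352
 },
 "pam": {
  "AA": 0.01,
  "AC": 0.01,
  "AG": 0.26,
  "AT": 0.01,
  "CA": 0.01,
  "CC": 0.005,
  "CG": 0.02,
  "CT": 0.008,
  "GA": 0.07,
  "GC": 0.02,
  "GG": 1.0,
  "GT": 0.03,
  "TA": 0.01,
  "TC": 0.008,
  "TG": 0.04,
  "TT": 0.008
 },
 "provenance": "SYNTHETIC representative CFD-style mismatch-activity factors: position-dependent decay toward the PAM-proximal seed with transition mismatches tolerated more than transversions, and per-PAM-tail factors with canonical GG = 1. These are NOT the published experimentally derived tables; substitute the published tables via ScoreTables.from_files for production use.",
 "schema_version": 1
}
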