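{
 "name": "quikcap64",
 "ordered_labels": [
  "FP1",
  "FPZ",
  "FP2",
  "AF3",
  "AF4",
  "F7",
  "F5",
  "F3",
  "F1",
  "FZ",
  "F2",
  "F4",
  "F6",
  "F8",
  "FT7",
  "FC5",
  "FC3",
  "FC1",
  "FCZ",
  "FC2",
  "FC4",
  "FC6",
  "FT8",
  "T7",
  "C5",
  "C3",
  "C1",
  "CZ",
  "C2",
  "C4",
  "C6",
  "T8",
  "M1",
  "TP7",
  "CP5",
  "CP3",
  "CP1",
  "CPZ",
  "CP2",
  "CP4",
  "CP6",
  "TP8",
  "M2",
  "P7",
  "P5",
  "P3",
  "P1",
  "PZ",
  "P2",
  "P4",
  "P6",
  "P8",
  "PO7",
  "PO5",
  "PO3",
  "POZ",
  "PO4",
  "PO6",
  "PO8",
  "I1",
  "O1",
  "OZ",
  "O2",
  "I2"
 ],
 "midline_labels": [
  "FPZ",
  "FZ",
  "FCZ",
  "CZ",
  "CPZ",
  "PZ",
  "POZ",
  "OZ"
 ],
 "symmetric_pairs": [
  [
   "FP1",
   "FP2"
  ],
  [
   "AF3",
   "AF4"
  ],
  [
   "F7",
   "F8"
  ],
  [
   "F5",
   "F6"
  ],
  [
   "F3",
   "F4"
  ],
  [
   "F1",
   "F2"
  ],
  [
   "FT7",
   "FT8"
  ],
  [
   "FC5",
   "FC6"
  ],
  [
   "FC3",
   "FC4"
  ],
  [
   "FC1",
   "FC2"
  ],
  [
   "T7",
   "T8"
  ],
  [
   "C5",
   "C6"
  ],
  [
   "C3",
   "C4"
  ],
  [
   "C1",
   "C2"
  ],
  [
   "M1",
   "M2"
  ],
  [
   "TP7",
   "TP8"
  ],
  [
   "CP5",
   "CP6"
  ],
  [
   "CP3",
   "CP4"
  ],
  [
   "CP1",
   "CP2"
  ],
  [
   "P7",
   "P8"
  ],
  [
   "P5",
   "P6"
  ],
  [
   "P3",
   "P4"
  ],
  [
   "P1",
   "P2"
  ],
  [
   "PO7",
   "PO8"
  ],
  [
   "PO5",
   "PO6"
  ],
  [
   "PO3",
   "PO4"
  ],
  [
   "I1",
   "I2"
  ],
  [
   "O1",
   "O2"
  ]
 ],
 "anterior_midline": "FPZ",
 "posterior_midline": "OZ",
 "canonical_directions": {
  "FP1": [
   0.892986,
   0.254274,
   0.371378
  ],
  "FPZ": [
   0.919787,
   0.0,
   0.392419
  ],
  "FP2": [
   0.892986,
   -0.254274,
   0.371378
  ],
  "AF3": [
   0.75354,
   0.292597,
   0.588697
  ],
  "AF4": [
   0.75354,
   -0.292597,
   0.588697
  ],
  "F7": [
   0.593115,
   0.754046,
   0.282185
  ],
  "F5": [
   0.68887,
   0.558631,
   0.461941
  ],
  "F3": [
   0.560989,
   0.456302,
   0.69071
  ],
  "F1": [
   0.621734,
   0.138578,
   0.770872
  ],
  "FZ": [
   0.789342,
   0.0,
   0.613954
  ],
  "F2": [
   0.621734,
   -0.138578,
   0.770872
  ],
  "F4": [
   0.560989,
   -0.456302,
   0.69071
  ],
  "F6": [
   0.68887,
   -0.558631,
   0.461941
  ],
  "F8": [
   0.593115,
   -0.754046,
   0.282185
  ],
  "FT7": [
   0.335304,
   0.870942,
   0.359209
  ],
  "FC5": [
   0.450716,
   0.690377,
   0.565892
  ],
  "FC3": [
   0.303598,
   0.548563,
   0.779042
  ],
  "FC1": [
   0.406947,
   0.290841,
   0.865913
  ],
  "FCZ": [
   0.288578,
   0.0,
   0.957456
  ],
  "FC2": [
   0.406947,
   -0.290841,
   0.865913
  ],
  "FC4": [
   0.303598,
   -0.548563,
   0.779042
  ],
  "FC6": [
   0.450716,
   -0.690377,
   0.565892
  ],
  "FT8": [
   0.335304,
   -0.870942,
   0.359209
  ],
  "T7": [
   0.03452,
   0.93033,
   0.365094
  ],
  "C5": [
   0.152678,
   0.760315,
   0.631356
  ],
  "C3": [
   0.01905,
   0.51376,
   0.857722
  ],
  "C1": [
   0.13279,
   0.258764,
   0.95677
  ],
  "CZ": [
   0.0,
   0.0,
   1.0
  ],
  "C2": [
   0.13279,
   -0.258764,
   0.95677
  ],
  "C4": [
   0.01905,
   -0.51376,
   0.857722
  ],
  "C6": [
   0.152678,
   -0.760315,
   0.631356
  ],
  "T8": [
   0.03452,
   -0.93033,
   0.365094
  ],
  "M1": [
   -0.481817,
   0.837177,
   0.258819
  ],
  "TP7": [
   -0.25148,
   0.856253,
   0.451208
  ],
  "CP5": [
   -0.140062,
   0.70795,
   0.692235
  ],
  "CP3": [
   -0.274955,
   0.481994,
   0.831914
  ],
  "CP1": [
   -0.165213,
   0.239017,
   0.956857
  ],
  "CPZ": [
   -0.330573,
   0.0,
   0.943781
  ],
  "CP2": [
   -0.165213,
   -0.239017,
   0.956857
  ],
  "CP4": [
   -0.274955,
   -0.481994,
   0.831914
  ],
  "CP6": [
   -0.140062,
   -0.70795,
   0.692235
  ],
  "TP8": [
   -0.25148,
   -0.856253,
   0.451208
  ],
  "M2": [
   -0.481817,
   -0.837177,
   0.258819
  ],
  "P7": [
   -0.696668,
   0.654798,
   0.293074
  ],
  "P5": [
   -0.500176,
   0.695008,
   0.516515
  ],
  "P3": [
   -0.532259,
   0.475197,
   0.700634
  ],
  "P1": [
   -0.445364,
   0.249955,
   0.859752
  ],
  "PZ": [
   -0.581294,
   0.0,
   0.813694
  ],
  "P2": [
   -0.445364,
   -0.249955,
   0.859752
  ],
  "P4": [
   -0.532259,
   -0.475197,
   0.700634
  ],
  "P6": [
   -0.500176,
   -0.695008,
   0.516515
  ],
  "P8": [
   -0.696668,
   -0.654798,
   0.293074
  ],
  "PO7": [
   -0.857251,
   0.445122,
   0.258819
  ],
  "PO5": [
   -0.726372,
   0.472043,
   0.499558
  ],
  "PO3": [
   -0.672823,
   0.235793,
   0.70122
  ],
  "POZ": [
   -0.778898,
   0.0,
   0.62715
  ],
  "PO4": [
   -0.672823,
   -0.235793,
   0.70122
  ],
  "PO6": [
   -0.726372,
   -0.472043,
   0.499558
  ],
  "PO8": [
   -0.857251,
   -0.445122,
   0.258819
  ],
  "I1": [
   -0.944018,
   0.204554,
   0.258819
  ],
  "O1": [
   -0.839178,
   0.231956,
   0.491912
  ],
  "OZ": [
   -0.913294,
   0.0,
   0.407302
  ],
  "O2": [
   -0.839178,
   -0.231956,
   0.491912
  ],
  "I2": [
   -0.944018,
   -0.204554,
   0.258819
  ]
 }
}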