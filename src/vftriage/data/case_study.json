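{
 "schema_version": "1",
 "experts": [
  "E1",
  "E2",
  "E3",
  "E4",
  "E5"
 ],
 "criteria": [
  "C1",
  "C2",
  "C3",
  "C4",
  "C5"
 ],
 "patients": [
  "P1",
  "P2",
  "P3",
  "P4",
  "P5"
 ],
 "peer_assessments": [
  [
   null,
   [
    0.7,
    0.8
   ],
   [
    0.5,
    0.8
   ],
   [
    0.9,
    1.0
   ],
   [
    0.6,
    0.9
   ]
  ],
  [
   [
    0.5,
    0.8
   ],
   null,
   [
    0.6,
    0.9
   ],
   [
    0.8,
    1.0
   ],
   [
    0.8,
    1.0
   ]
  ],
  [
   [
    0.5,
    0.6
   ],
   [
    0.8,
    1.0
   ],
   null,
   [
    1.0,
    1.0
   ],
   [
    0.7,
    0.8
   ]
  ],
  [
   [
    0.6,
    0.7
   ],
   [
    0.7,
    0.9
   ],
   [
    0.7,
    1.0
   ],
   null,
   [
    0.8,
    0.9
   ]
  ],
  [
   [
    0.7,
    0.8
   ],
   [
    0.6,
    0.8
   ],
   [
    0.6,
    0.9
   ],
   [
    0.7,
    0.9
   ],
   null
  ]
 ],
 "criteria_assessments": [
  [
   [
    0.4,
    0.7
   ],
   [
    0.8,
    1.0
   ],
   [
    0.2,
    0.5
   ],
   [
    0.5,
    0.9
   ],
   [
    0.7,
    0.9
   ]
  ],
  [
   [
    0.6,
    0.8
   ],
   [
    0.6,
    0.9
   ],
   [
    0.4,
    0.7
   ],
   [
    0.6,
    0.8
   ],
   [
    0.5,
    0.8
   ]
  ],
  [
   [
    0.5,
    0.8
   ],
   [
    0.8,
    0.9
   ],
   [
    0.5,
    0.8
   ],
   [
    0.3,
    0.5
   ],
   [
    0.6,
    1.0
   ]
  ],
  [
   [
    0.7,
    0.8
   ],
   [
    1.0,
    1.0
   ],
   [
    0.5,
    0.7
   ],
   [
    0.6,
    0.7
   ],
   [
    0.5,
    0.7
   ]
  ],
  [
   [
    0.6,
    0.8
   ],
   [
    0.6,
    0.9
   ],
   [
    0.6,
    0.8
   ],
   [
    0.7,
    0.8
   ],
   [
    0.4,
    0.6
   ]
  ]
 ],
 "patient_assessments": {
  "E1": [
   [
    [
     0.3,
     0.6
    ],
    [
     0.6,
     0.9
    ],
    [
     0.7,
     0.7
    ],
    [
     0.3,
     0.6
    ],
    [
     0.8,
     0.9
    ]
   ],
   [
    [
     0.4,
     0.9
    ],
    [
     0.7,
     0.7
    ],
    [
     0.8,
     1.0
    ],
    [
     0.6,
     0.9
    ],
    [
     0.3,
     0.7
    ]
   ],
   [
    [
     0.2,
     0.7
    ],
    [
     0.3,
     0.7
    ],
    [
     0.4,
     0.5
    ],
    [
     0.6,
     0.9
    ],
    [
     0.4,
     0.5
    ]
   ],
   [
    [
     0.7,
     0.9
    ],
    [
     0.4,
     0.9
    ],
    [
     0.3,
     0.9
    ],
    [
     0.4,
     0.8
    ],
    [
     0.7,
     1.0
    ]
   ],
   [
    [
     0.6,
     0.8
    ],
    [
     0.8,
     0.9
    ],
    [
     0.5,
     0.7
    ],
    [
     0.9,
     1.0
    ],
    [
     0.5,
     0.8
    ]
   ]
  ],
  "E2": [
   [
    [
     0.5,
     0.7
    ],
    [
     0.7,
     0.8
    ],
    [
     0.5,
     0.7
    ],
    [
     0.5,
     0.6
    ],
    [
     0.7,
     0.7
    ]
   ],
   [
    [
     0.6,
     0.9
    ],
    [
     0.6,
     0.9
    ],
    [
     0.7,
     0.8
    ],
    [
     0.7,
     0.9
    ],
    [
     0.5,
     0.6
    ]
   ],
   [
    [
     0.7,
     0.8
    ],
    [
     0.4,
     0.6
    ],
    [
     0.6,
     0.7
    ],
    [
     0.4,
     0.8
    ],
    [
     0.6,
     0.7
    ]
   ],
   [
    [
     0.7,
     0.9
    ],
    [
     0.6,
     0.8
    ],
    [
     0.3,
     0.8
    ],
    [
     0.7,
     0.8
    ],
    [
     0.6,
     1.0
    ]
   ],
   [
    [
     0.8,
     0.8
    ],
    [
     0.7,
     0.7
    ],
    [
     0.6,
     0.9
    ],
    [
     0.7,
     0.7
    ],
    [
     0.5,
     0.9
    ]
   ]
  ],
  "E3": [
   [
    [
     0.6,
     0.7
    ],
    [
     0.8,
     0.8
    ],
    [
     0.6,
     0.9
    ],
    [
     0.6,
     0.6
    ],
    [
     0.8,
     0.9
    ]
   ],
   [
    [
     0.5,
     1.0
    ],
    [
     0.5,
     0.7
    ],
    [
     0.8,
     1.0
    ],
    [
     0.6,
     0.9
    ],
    [
     0.6,
     0.8
    ]
   ],
   [
    [
     0.6,
     0.6
    ],
    [
     0.6,
     0.8
    ],
    [
     0.7,
     0.7
    ],
    [
     0.5,
     0.7
    ],
    [
     0.7,
     0.7
    ]
   ],
   [
    [
     0.6,
     0.9
    ],
    [
     0.5,
     1.0
    ],
    [
     0.4,
     0.9
    ],
    [
     0.9,
     0.9
    ],
    [
     0.5,
     0.8
    ]
   ],
   [
    [
     0.7,
     0.7
    ],
    [
     0.6,
     0.7
    ],
    [
     0.8,
     0.9
    ],
    [
     0.5,
     0.8
    ],
    [
     0.7,
     1.0
    ]
   ]
  ],
  "E4": [
   [
    [
     0.3,
     0.6
    ],
    [
     0.7,
     0.9
    ],
    [
     0.4,
     0.9
    ],
    [
     0.8,
     0.8
    ],
    [
     0.6,
     0.9
    ]
   ],
   [
    [
     0.5,
     0.9
    ],
    [
     0.7,
     0.7
    ],
    [
     0.5,
     0.8
    ],
    [
     0.5,
     0.9
    ],
    [
     0.6,
     0.8
    ]
   ],
   [
    [
     0.8,
     0.9
    ],
    [
     0.3,
     0.9
    ],
    [
     0.8,
     0.9
    ],
    [
     0.4,
     1.0
    ],
    [
     0.7,
     0.8
    ]
   ],
   [
    [
     0.3,
     0.5
    ],
    [
     0.8,
     0.8
    ],
    [
     0.6,
     0.8
    ],
    [
     0.7,
     0.8
    ],
    [
     0.6,
     1.0
    ]
   ],
   [
    [
     0.4,
     0.4
    ],
    [
     0.3,
     0.9
    ],
    [
     0.6,
     0.7
    ],
    [
     0.7,
     0.9
    ],
    [
     0.8,
     0.9
    ]
   ]
  ],
  "E5": [
   [
    [
     0.5,
     0.7
    ],
    [
     0.6,
     0.9
    ],
    [
     0.2,
     1.0
    ],
    [
     0.7,
     0.9
    ],
    [
     0.9,
     1.0
    ]
   ],
   [
    [
     0.8,
     1.0
    ],
    [
     0.5,
     0.7
    ],
    [
     0.4,
     0.9
    ],
    [
     0.4,
     1.0
    ],
    [
     0.7,
     1.0
    ]
   ],
   [
    [
     0.7,
     0.8
    ],
    [
     0.3,
     0.9
    ],
    [
     0.7,
     0.9
    ],
    [
     0.7,
     0.9
    ],
    [
     0.6,
     0.8
    ]
   ],
   [
    [
     0.6,
     0.7
    ],
    [
     0.7,
     0.9
    ],
    [
     0.4,
     0.9
    ],
    [
     0.6,
     0.9
    ],
    [
     0.5,
     0.7
    ]
   ],
   [
    [
     0.2,
     0.3
    ],
    [
     0.1,
     0.7
    ],
    [
     0.4,
     0.8
    ],
    [
     0.5,
     0.7
    ],
    [
     0.7,
     0.9
    ]
   ]
  ]
 },
 "fixed_expert_weights": [
  0.12,
  0.19,
  0.16,
  0.3,
  0.23
 ],
 "fixed_criteria_weights": [
  0.21,
  0.39,
  0.09,
  0.16,
  0.15
 ]
}
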