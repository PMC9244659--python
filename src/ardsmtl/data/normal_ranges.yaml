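# Clinical normal ranges used for coarse feature normalization.
#
# For each time-varying input the center of the adult normal range serves as an
# approximate mean and half the range width as an approximate SD, so a value at
# the upper bound normalizes to +1 and one at the lower bound to -1.
# version: 1
systolic_bp:      {low: 90.0,   high: 120.0, unit: mmHg}
diastolic_bp:     {low: 60.0,   high: 80.0,  unit: mmHg}
heart_rate:       {low: 60.0,   high: 100.0, unit: bpm}
pao2:             {low: 75.0,   high: 100.0, unit: mmHg}
respiratory_rate: {low: 12.0,   high: 20.0,  unit: /min}
spo2:             {low: 95.0,   high: 100.0, unit: "%"}
temperature:      {low: 36.5,   high: 37.5,  unit: degC}
glucose:          {low: 70.0,   high: 100.0, unit: mg/dL}
bilirubin:        {low: 0.2,    high: 1.2,   unit: mg/dL}
wbc:              {low: 4.0,    high: 11.0,  unit: 1e9/L}
rbc:              {low: 4.2,    high: 5.9,   unit: 1e12/L}
lymphocytes:      {low: 20.0,   high: 40.0,  unit: "%"}
alt:              {low: 7.0,    high: 56.0,  unit: U/L}
inr:              {low: 0.8,    high: 1.2,   unit: ratio}
ph:               {low: 7.35,   high: 7.45,  unit: pH}
bun:              {low: 7.0,    high: 20.0,  unit: mg/dL}
creatinine:       {low: 0.6,    high: 1.2,   unit: mg/dL}
platelets:        {low: 150.0,  high: 400.0, unit: 1e9/L}
neutrophils:      {low: 40.0,   high: 70.0,  unit: "%"}
monocytes:        {low: 2.0,    high: 8.0,   unit: "%"}
hematocrit:       {low: 36.0,   high: 50.0,  unit: "%"}
lactate:          {low: 0.5,    high: 2.2,   unit: mmol/L}
ast:              {low: 10.0,   high: 40.0,  unit: U/L}
# SIRS is a computed 0-4 score; 0-1 is unremarkable, >2 enters the sepsis
# definition. The pseudo normal range below centers it at 1 with unit SD.
sirs:             {low: 0.0,    high: 2.0,   unit: score}
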