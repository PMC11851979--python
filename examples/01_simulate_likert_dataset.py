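"""Simulate one Likert-predictor dataset from a design cell.

Builds the medium-complexity 3-IV cell with small linear and large
nonlinear coefficients at unit noise, draws coefficients from the stated
uniform ranges, and generates n=1000 observations.
"""

import numpy as np

from mssr import ConditionSpec, dataset_to_frame, draw_coefficients, generate_dataset

condition = ConditionSpec(complexity=2, n_iv=3, linear_level="small",
                          nonlinear_level="large", error_coef=1)
coefs = draw_coefficients(condition, seed=2024)
dataset = generate_dataset(condition, n=1000, coefs=coefs, seed=7)

df = dataset_to_frame(dataset)
print("condition id:", condition.condition_id)
print("linear coefficients:", np.round(coefs.cof, 3))
print("nonlinear coefficients:", np.round(coefs.conf, 3))
print(df.head(), "\n")
for col in ("X1", "X2", "X3"):
    freq = df[col].value_counts(normalize=True).sort_index().round(3)
    print(f"{col} category frequencies:", dict(freq))

# The X columns are the observed 1..5 Likert codes (ceiling of latent
# N(3,1) scores, clipped); Y is continuous, computed from the latent
# values, so the discretization is the only predictor measurement error.
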