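"""Model recovery: can AIC tell the two models apart on simulated data?

Simulates single sessions from each model with randomized parameters plus
motor noise, refits both models, and prints the confusion matrix of win
proportions (rows: generating model; columns: winning model). Diagonal
dominance means the candidates are distinguishable. Scaled down to run in
seconds; increase n_per_condition for a tighter estimate.
"""

from stridelearn import model_recovery

cm = model_recovery(("su", "ab"), n_per_condition=10, seed=3, n_restarts=6)

for cond in ("constant", "LV", "HV", "combined"):
    print(f"{cond} (AIC):")
    print(cm.matrix(cond, "aic").round(2), end="\n\n")

print("combined (BIC):")
print(cm.matrix("combined", "bic").round(2))
print(
    f"\nAIC discriminability (diag - offdiag): {cm.discriminability('aic'):.2f}; "
    f"BIC: {cm.discriminability('bic'):.2f}.\n"
    "BIC's heavier penalty on the 4-parameter S+U model typically reduces\n"
    "discriminability, which is why AIC is the selection criterion."
)
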