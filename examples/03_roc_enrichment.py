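"""ROC/AUC enrichment of actives over decoys for a docking setup.

Generates Gaussian score lists for known actives and decoys at two levels of
separation and reports how well the (synthetic) docking ranks actives first.
"""

from cbdeval import generate_actives_decoys, roc_curve

for separation in (2.0, 0.5):
    inp = generate_actives_decoys(
        n_act=150, n_dec=80, separation=separation, noise_sd=1.0, seed=7
    )
    curve = roc_curve(inp)
    print(
        f"separation {separation:.1f} score units: AUC = {curve.auc:.3f} "
        f"({inp.active_scores.size} actives vs {inp.decoy_scores.size} decoys, "
        f"{len(curve.points)} ROC points)"
    )
print(
    "\nAUC 0.5 means the scores cannot tell actives from decoys; 1.0 means\n"
    "every active outranks every decoy. Ties contribute half credit, so the\n"
    "trapezoidal area equals the Mann-Whitney pair-counting statistic."
)
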