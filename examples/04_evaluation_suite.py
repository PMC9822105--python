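"""The evaluation suite on a hand-sized example: per-protein F1, the Fmax
threshold sweep, IC-weighted Fmax and the Friedman/Nemenyi comparison.
"""

import numpy as np

from gotriplet import (
    fmax_sweep,
    friedman_nemenyi,
    icw_fmax,
    protein_f1,
)
from gotriplet.ontology import AnnotationSet

# per-protein F1 from prediction/truth sets: the same arithmetic as a
# published case study (15 correct, 0 wrong vs 18 native terms -> 0.909)
truth = {f"t{i}" for i in range(18)}
pred = {f"t{i}" for i in range(15)}
print(f"per-protein F1 = {protein_f1(pred, truth):.3f}")

# threshold sweep over two proteins
annotations = AnnotationSet(
    {"A": frozenset({"x", "y"}), "B": frozenset({"y"})}, "BP", True
)
scores = {"A": {"x": 0.9, "y": 0.6, "z": 0.2}, "B": {"y": 0.8, "x": 0.3}}
fmax, t_star, curve = fmax_sweep(scores, annotations, thresholds="exact")
print(f"Fmax = {fmax:.3f} at t* = {t_star:.2f}")

# IC weighting: down-weights shallow terms ('y' is common, 'x' is rare)
ic = {"x": 4.0, "y": 0.5, "z": 4.0}
f_icw, _ = icw_fmax(scores, annotations, ic, thresholds="exact")
print(f"ICW-Fmax = {f_icw:.3f}")

# method comparison: 15 proteins x 3 methods, method 0 dominates
rng = np.random.default_rng(0)
f1_matrix = rng.uniform(0.0, 0.5, size=(15, 3))
f1_matrix[:, 0] += 0.4
p, pairwise = friedman_nemenyi(f1_matrix)
print(f"Friedman p = {p:.2e}; Nemenyi p(method 0 vs 1) = {pairwise[0, 1]:.3f}")
# a small Friedman p says the methods differ somewhere; the Nemenyi matrix
# says which pairs differ at the individual-protein level.
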