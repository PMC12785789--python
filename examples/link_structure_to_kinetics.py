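"""Exploratory multivariate view of wood structure vs extraction kinetics.

Assembles the default 3 x 11 toast-level feature matrix (kinetic
parameters + structural descriptors), runs standardized PCA and prints
Spearman rank correlations of selected descriptor pairs.  With three
observations this is descriptive, not inferential.
"""

from ecikin import run_pca, spearman_rho, standardize
from ecikin.synthetic import assemble_feature_matrix

fm = assemble_feature_matrix()
print(fm.round(3), "\n")

res = run_pca(standardize(fm))
print("explained variance: PC1 %.1f%%, PC2 %.1f%%" % tuple(res.explained_pct))
print("\nscores (toast levels in PC space):")
print(res.scores.round(2), "\n")

for a, b in [("a1", "a2"), ("a1", "k1"), ("contrast", "homogeneity")]:
    print(f"Spearman rho({a}, {b}) = {spearman_rho(fm[a], fm[b]):+.2f}")
# rho(a1, a2) = +1: extraction and adsorption capacity fall together as
# toasting degrades the active sites; rho(a1, k1) = -1: what is extracted
# faster (intense toast) is extracted in smaller total amount.
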