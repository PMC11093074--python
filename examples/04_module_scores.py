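"""Per-cell module scores against expression-matched controls.

Simulates a population in which half the cells induce a 20-gene program,
then scores that program per cell: set-gene mean expression minus the mean
of controls drawn from the same average-expression bins.
"""

import numpy as np

from geneflows import ExpressionMatrix, module_score

rng = np.random.default_rng(3)
n_genes, n_cells = 800, 400
counts = rng.poisson(1.0, size=(n_genes, n_cells))
program = np.arange(20)
active = np.arange(n_cells // 2)
counts[np.ix_(program, active)] += rng.poisson(4.0, size=(20, n_cells // 2))

rna = ExpressionMatrix(counts=counts,
                       gene_ids=[f"g{i}" for i in range(n_genes)],
                       cell_ids=[f"cell{i}" for i in range(n_cells)])
score = module_score(rna, [f"g{i}" for i in program], n_bins=24, n_ctrl=100, seed=0)
print(f"mean score, induced half:    {score.iloc[:200].mean():+.3f}")
print(f"mean score, background half: {score.iloc[200:].mean():+.3f}")
# Scores are centred near 0 for cells without the program and strongly
# positive where the program is induced; matched controls remove the
# depth/abundance component.
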