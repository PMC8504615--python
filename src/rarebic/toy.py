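"""A small synthetic worked example.

A 15-gene x 12-cell integer matrix on the signed log scale, built so the
two optimization regimes behave in instructively different ways:

* the unconstrained max-sum submatrix optimum (kappa = 0, mu = 1) is a
  relatively large, unspecific bicluster — nine genes over seven
  background cells including c2 and c12 — whose columns contribute
  positively in sum despite negative entries scattered inside;
* the constrained search (kappa = 1, mu = 10%) returns exactly the
  3 cells {c5, c6, c7} with their 5 dedicated markers
  {g5, g8, g9, g12, g15}.  Three of the markers (g5, g9, g15) have one
  out-of-cluster expression each; gene g3 is expressed in the cluster
  but is excluded because its out-of-cluster positive mass cancels its
  in-cluster contribution.

The values are synthetic (authored for this package) and verified
against the exhaustive solver in the test suite.
"""

from __future__ import annotations

import numpy as np

from .matrix import ExpressionMatrix

_TOY = [
    #  c1  c2  c3  c4  c5  c6  c7  c8  c9 c10 c11 c12
    [   2,  2,  2, -1, -1, -2, -1, -1,  2,  2, -1, -1],  # g1
    [  -1,  2,  2, -1, -2, -1, -1, -1,  2,  2,  2, -1],  # g2
    [   2, -1, -1, -1,  2,  2,  2, -1,  2, -1,  2, -1],  # g3
    [  -1, -1,  2, -1, -1, -1, -2, -1,  2,  2,  2,  2],  # g4
    [  -1,  1, -2, -1,  3,  2,  2, -1, -2, -1, -1, -1],  # g5
    [   2, -1, -1, -1, -1, -1, -1, -1,  2,  2,  2,  2],  # g6
    [   2,  2, -1, -1, -2, -1, -1, -1, -1,  2,  2,  2],  # g7
    [  -2, -1, -1, -2,  2,  3,  2, -1, -1, -2, -1, -1],  # g8
    [  -1, -2, -1, -1,  2,  2,  3, -1, -1,  1, -2, -1],  # g9
    [   2,  2,  2, -1, -1, -1, -2, -1, -1, -1,  2,  2],  # g10
    [   2,  2,  2, -1, -1, -2, -1, -1,  2, -1, -1,  2],  # g11
    [  -1, -1, -2, -1,  3,  2,  3, -2, -1, -1, -1, -2],  # g12
    [   2,  2,  2, -1, -1, -1, -1, -1,  2,  2, -1, -2],  # g13
    [   1, -1, -1,  2, -1, -1, -1, -1, -1,  2,  1, -1],  # g14
    [  -2, -1, -1, -1,  2,  2,  2, -1, -2, -1, -1,  1],  # g15
]

#: cells and marker genes of the planted specific bicluster
TOY_CELLS = ["c5", "c6", "c7"]
TOY_GENES = ["g5", "g8", "g9", "g12", "g15"]


def toy_matrix() -> ExpressionMatrix:
    """The 15 x 12 worked-example matrix (already on the signed log scale)."""
    return ExpressionMatrix(np.array(_TOY, dtype=float), normalized=True)
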