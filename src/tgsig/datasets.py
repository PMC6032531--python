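"""Built-in worked-example data.

The package's worked example is the published sixteen-gene major-gene
table from the rheumatoid-arthritis TG-tablet response study this method
originates from: network topology (degree, closeness, betweenness) and
differential-expression statistics (p-value, responder/non-responder
fold change) for the sixteen nodes that exceeded all three topology
medians. Running the candidate filter on it yields the six-gene
signature MX1, OASL, SPINK1, CRK, GRAPL, RNF2, and the published model
weights and threshold for those genes define the reference scorer.
"""

from __future__ import annotations

import pandas as pd

from .pls import PLSSignatureClassifier

_MAJOR_GENE_ROWS = [
    # gene, degree, closeness, betweenness, p_value, fc, direction
    ("ACTL6B", 2, 2.69, 1.37, 0.04, 0.82, "down"),
    ("CRK", 5, 2.71, 7.99, 0.02, 1.52, "up"),
    ("GHR", 3, 2.69, 1.37, 0.03, 1.25, "up"),
    ("GRAPL", 3, 2.73, 12.48, 0.02, 1.59, "up"),
    ("IGF1", 4, 2.69, 1.43, 0.02, 0.81, "down"),
    ("MX1", 5, 2.72, 11.21, 0.02, 0.55, "down"),
    ("OASL", 5, 2.70, 5.02, 0.01, 0.62, "down"),
    ("RAB28", 2, 2.69, 2.64, 0.02, 1.22, "up"),
    ("RAB33B", 2, 2.66, 1.37, 0.02, 1.24, "up"),
    ("RNF2", 3, 2.68, 2.64, 0.02, 1.65, "up"),
    ("RNF8", 2, 2.66, 1.37, 0.04, 0.80, "down"),
    ("RPL23", 3, 2.67, 1.37, 0.04, 0.79, "down"),
    ("SPINK1", 3, 2.71, 6.66, 0.02, 0.63, "down"),
    ("UST", 3, 2.68, 2.64, 0.04, 1.23, "up"),
    ("VAV2", 2, 2.68, 1.37, 0.03, 1.21, "up"),
    ("ZNF384", 2, 2.66, 1.37, 0.01, 1.23, "up"),
]

SIGNATURE_GENES = ["MX1", "OASL", "SPINK1", "CRK", "GRAPL", "RNF2"]
SIGNATURE_WEIGHTS = [-0.4694, -0.2494, -0.5592, 0.3429, 0.4054, 0.3504]
SIGNATURE_THRESHOLD = -0.03


def load_major_gene_table() -> pd.DataFrame:
    """The sixteen published major genes with topology and DE statistics.

    Columns: gene_id, degree, closeness, betweenness, p_value, fc,
    direction — indexed by gene, ready for
    :func:`tgsig.network.select_candidates` and
    :func:`tgsig.network.select_major_genes`.
    """
    df = pd.DataFrame(
        _MAJOR_GENE_ROWS,
        columns=["gene_id", "degree", "closeness", "betweenness", "p_value", "fc", "direction"],
    )
    return df.set_index("gene_id", drop=False)


def load_reference_model() -> PLSSignatureClassifier:
    """The published six-gene scorer: fixed weights and threshold T = -0.03.

    Center/scale are identity (mean 0, SD 1): the model expects
    expression already standardized the way its weights were derived,
    and is intended as a scoring fixture, not as a model refittable to
    new cohorts.
    """
    import numpy as np

    model = PLSSignatureClassifier(threshold=SIGNATURE_THRESHOLD)
    model.gene_ids_ = list(SIGNATURE_GENES)
    model.center_ = np.zeros(len(SIGNATURE_GENES))
    model.scale_ = np.ones(len(SIGNATURE_GENES))
    model.weights_ = np.asarray(SIGNATURE_WEIGHTS, dtype=float)
    model.threshold_ = SIGNATURE_THRESHOLD
    model.threshold_result_ = None
    model.classes_ = np.array(sorted([model.negative_label, model.positive_label]))
    return model
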