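"""Hand-controllable model/feature stand-ins for unit tests."""

import numpy as np


class StubFeatures:
    """Maps each compound to an index so stub models can key activations
    off pair identity."""

    def __init__(self, ids):
        self.index = {d: i for i, d in enumerate(ids)}

    def pair_vector(self, a, b):
        return np.array([self.index[a], self.index[b]], dtype=float)

    def pair_matrix(self, pairs):
        return np.vstack([self.pair_vector(a, b) for a, b in pairs])


class StubModel:
    """Activation table keyed by ordered (index_a, index_b); pairs absent
    from the table activate nothing."""

    def __init__(self, table, output_dim=86):
        self.table = table
        self.output_dim = output_dim

    def predict_activations(self, X):
        X = np.atleast_2d(X)
        out = np.zeros((X.shape[0], self.output_dim))
        for row, x in zip(out, X):
            for type_id, score in self.table.get((int(x[0]), int(x[1])), {}).items():
                row[type_id - 1] = score
        return out
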