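import numpy as np
import pandas as pd

from hcmfs import FeatureTable


def make_numeric_table(X, y, names=None) -> FeatureTable:
    """Plain numeric FeatureTable from arrays (test helper)."""
    X = np.asarray(X, dtype=float)
    names = names or [f"f{i}" for i in range(X.shape[1])]
    return FeatureTable.from_dataframe(pd.DataFrame(X, columns=names), np.asarray(y))
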