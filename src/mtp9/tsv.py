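"""TSV interchange conventions shared by all pipeline stages.

Headers mandatory, UTF-8, '.' decimal, literal ``NA`` for missing.
Floats are written with %.10g so reruns are byte-identical.
"""

from __future__ import annotations

import pandas as pd

NA_REP = "NA"
FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[NA_REP], keep_default_na=False, **kwargs
    )
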