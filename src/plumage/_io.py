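"""Delimited-text reading shared by the table modules."""

import pandas as pd


def read_table(path) -> pd.DataFrame:
    """CSV/TSV reader with separator sniffing and exact float round-trip."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")
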