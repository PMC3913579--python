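"""Small bundled reference tables.

``published_screen_hits`` is the published hit list of a C. glutamicum
transposon-mutant metabolic screen: the 15 mutants flagged for significant
changes in TCA-cycle and/or glutamate-associated metabolites, with insertion
position, affected locus, operon membership, EC number, wild-type profile
correlation, relative growth (%OD) and the two pathway flag columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def published_screen_hits() -> pd.DataFrame:
    """Published pathway-screen hit list (15 mutants, TCA/GLU flags)."""
    with resources.files("tnscreen.data").joinpath("published_screen_hits.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for col in ("TCA", "GLU", "operon"):
        df[col] = df[col].map({"true": True, "false": False, True: True, False: False})
        df[col] = df[col].astype(bool)
    return df
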