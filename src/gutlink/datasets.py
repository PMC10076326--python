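"""Bundled reference datasets.

``load_published_gene_screen`` returns the published cross-diet
correlation screen over the 66 diet-shared differentially expressed
genes (one row per printed gene entry, including one duplicated liver
row exactly as printed): per gene, Pearson r and p against the
absolute (ΔBW(g)) and slope (ΔBW(s)) weight contrasts over the six
diets, plus the published bold/selected flag. It is the reference
input for validating the p-from-r computation and the selection rule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_published_gene_screen", "parse_printed_p"]


def parse_printed_p(value: str) -> tuple[float, bool]:
    """Parse a printed p entry; returns (value, is_upper_bound).

    Entries like ``<0.01`` report an upper bound rather than a value.
    """
    s = str(value).strip()
    if s.startswith("<"):
        return float(s[1:]), True
    return float(s), False


def load_published_gene_screen() -> pd.DataFrame:
    """The 66-row published gene–weight correlation screen.

    Columns: tissue, gene, r_abs, p_abs (string, may be ``<0.01``),
    r_slope, p_slope (string), bold (bool).
    """
    ref = resources.files("gutlink.data").joinpath("published_gene_screen.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(
            path, sep="\t", dtype={"p_abs": str, "p_slope": str, "gene": str}
        )
    df["bold"] = df["bold"].astype(bool)
    return df
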