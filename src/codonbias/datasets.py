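"""Published codon-usage tables of the *Delphinium grandiflorum* chloroplast.

Three small tables from the published analysis of the 51 qualified CDSs of
the *D. grandiflorum* chloroplast genome (GenBank MN556604) ship with the
package as TSV:

* ``dgrandiflorum_cp_codon_usage`` — genome-wide pooled codon counts with
  the published RSCU values and the high-frequency (top-RSCU-per-family)
  flags;
* ``dgrandiflorum_cp_gene_indices`` — per-gene GC, GC3, GC3s and ENC for the
  51 CDSs (values as printed, 2 d.p.);
* ``dgrandiflorum_cp_expression_codon_usage`` — pooled codon counts and RSCU
  of the high- and low-expression (ENC-ranked) gene sets, with the published
  dRSCU and high-expression flags.

These are reference inputs and regression anchors; the published RSCU and
dRSCU columns are recomputable from the count columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codon_model import CodonTable, standard_table
from .metrics import CodonCountTable, counts_from_mapping


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("codonbias.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_codon_usage() -> pd.DataFrame:
    """Genome-wide pooled codon usage (amino_acid, codon, count, rscu,
    high_frequency)."""
    return _load("dgrandiflorum_cp_codon_usage.tsv")


def load_gene_indices() -> pd.DataFrame:
    """Per-gene indices of the 51 CDSs (gene, gc, gc3, gc3s, enc)."""
    return _load("dgrandiflorum_cp_gene_indices.tsv")


def load_expression_codon_usage() -> pd.DataFrame:
    """Codon usage of the high/low expression gene sets with published
    dRSCU values and high-expression flags."""
    return _load("dgrandiflorum_cp_expression_codon_usage.tsv")


def pooled_counts(table: CodonTable | None = None) -> CodonCountTable:
    """The genome-wide pooled codon counts as a CodonCountTable."""
    table = table or standard_table()
    df = load_codon_usage()
    return counts_from_mapping(
        dict(zip(df["codon"], df["count"])), table, scope="pooled"
    )


def expression_counts(
    table: CodonTable | None = None,
) -> tuple[CodonCountTable, CodonCountTable]:
    """(high-expression, low-expression) pooled codon count tables."""
    table = table or standard_table()
    df = load_expression_codon_usage()
    high = counts_from_mapping(
        dict(zip(df["codon"], df["high_count"])), table, scope="high_expression"
    )
    low = counts_from_mapping(
        dict(zip(df["codon"], df["low_count"])), table, scope="low_expression"
    )
    return high, low
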