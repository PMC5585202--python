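"""Bundled reference tables.

The package ships the published whole-network parameter table for the
forelimb musculoskeletal networks of 22 mammalian taxa (19 primates
plus the outgroups *Mus*, *Tupaia* and *Cynocephalus*): node count N,
link count K, density D, clustering coefficient C, characteristic path
length L, heterogeneity H, and connectivity-module count M, with a
coarse clade label per taxon.  The underlying adjacency matrices are
dissection-derived supplementary data and are not redistributed here;
the table supports consistency checks (the density identity
D = 2K/(N(N-1))), clade summaries, and validation of user-supplied
matrices.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_primate_forelimb_parameters", "HOMINOID_TAXA"]

HOMINOID_TAXA = (
    "Hylobates lar",
    "Pongo pygmaeus",
    "Gorilla gorilla",
    "Pan troglodytes",
    "Pan paniscus",
    "Homo sapiens",
)


def load_primate_forelimb_parameters() -> pd.DataFrame:
    """Published forelimb network parameters for 22 taxa.

    Returns a DataFrame with columns
    ``taxon, clade, N, K, D, C, L, H, M`` — the values as printed in
    the source study (D, C, L, H rounded to 3 decimals there).
    """
    with resources.files("anna.data").joinpath(
        "primate_forelimb_parameters.csv"
    ).open() as fh:
        return pd.read_csv(fh)
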