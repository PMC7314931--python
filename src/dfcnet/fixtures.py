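"""Packaged reference tables for the 17-node language network.

Three small TSV fixtures ship with the package:

* ``table1_nodes.tsv`` — the 17 language-network nodes (7 derived from the
  Broca seed, 10 from the Wernicke seed) with peak MNI coordinates, cluster
  sizes and peak t-values.
* ``table2_dfc.tsv`` — the 22 edge-in-state connectivity comparisons that
  separated early from late bilinguals (group means +- SD, permutation p,
  Cohen's d).
* ``table3_topology.tsv`` — the four weighted graph metrics (Cw, Lw, Eglob,
  Eloc) per dFC state for both groups.

Files are integrity-checked on load.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

_CHECKSUMS = {
    "table1_nodes.tsv": "4d8a6b2052519a6002ed7264b008dbb7528870c26470248c8a1a0f928c0babe6",
    "table2_dfc.tsv": "cf430549c74d1efa79bbd1574f895a8465c25ac519ea32ab8fc947f0a093ff88",
    "table3_topology.tsv": "f0dff720308988a4c05a82e8d3d968ab9e7c53bebb55591b235b12f0bbf9b956",
}

#: Seed spheres used to grow the network (MNI mm, 3-mm radius).
BROCA_SEED_MNI = (-53.0, 20.0, 15.0)
WERNICKE_SEED_MNI = (-51.0, -51.0, 30.0)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("dfcnet.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"fixture {name} failed its checksum ({digest})")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


def load_node_table() -> pd.DataFrame:
    """17-row node table: seed of origin, node name, peak MNI coordinate."""
    df = _read("table1_nodes.tsv")
    df["radius_mm"] = 3.0
    return df


def load_dfc_table() -> pd.DataFrame:
    """22 significant edge-in-state group comparisons (connectivity strength)."""
    return _read("table2_dfc.tsv")


def load_topology_table() -> pd.DataFrame:
    """Graph metric (Cw, Lw, Eglob, Eloc) by state group comparisons."""
    return _read("table3_topology.tsv")


def load_fixtures() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All three packaged tables: (node table, dFC table, topology table)."""
    return load_node_table(), load_dfc_table(), load_topology_table()


def default_node_names() -> list[str]:
    """Node names in canonical (fixture) order."""
    return list(load_node_table()["node"])
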