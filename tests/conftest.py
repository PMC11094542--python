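import numpy as np
import pandas as pd
import pytest

from crust_assembly.io_core import (AsvTable, EnzymeActivities, SampleMetadata,
                                    TaxonomyTable, tree_from_newick)


@pytest.fixture
def small_counts():
    return AsvTable(pd.DataFrame(
        [[10, 5, 0, 1], [2, 8, 4, 2], [0, 3, 9, 6]],
        index=["s1", "s2", "s3"], columns=["a", "b", "c", "d"]))


@pytest.fixture
def cherry_tree():
    return tree_from_newick("((a:1,b:1):1,c:2);")


@pytest.fixture
def six_tip_trees():
    """Three fixed six-tip trees with hand-checkable branch lengths."""
    return [
        tree_from_newick("(((a:1,b:1):1,(c:1,d:1):1):1,(e:2,f:2):1);"),
        tree_from_newick("((a:1,(b:0.5,c:0.5):0.5):2,((d:1,e:1):1,f:2):1);"),
        tree_from_newick("(a:3,(b:2,(c:1,(d:0.5,(e:0.25,f:0.25):0.25):0.5):1):1);"),
    ]


@pytest.fixture
def enzyme_table():
    return EnzymeActivities(pd.DataFrame(
        {"AG": [10, 12], "BG": [50, 40], "XS": [20, 15], "CB": [10, 15],
         "NAG": [20, 25], "LAP": [10, 8], "AP": [40, 30]},
        index=["s1", "s2"]))


@pytest.fixture
def metadata_two_sites():
    rows = {}
    rng = np.random.default_rng(0)
    for i in range(6):
        rows[f"s{i + 1}"] = {
            "site": "A" if i < 3 else "B",
            "pH": 7.5 + 0.1 * rng.normal(), "EC": 150.0, "SWC": 10.0,
            "SOC": 40.0 + i, "TN": 4.0, "NH4_N": 40.0, "NO3_N": 15.0,
            "TP": 0.8, "AP_avail": 40.0, "AK": 250.0,
        }
    return SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"))


@pytest.fixture
def taxonomy_simple():
    rows = {
        "a": {"kingdom": "Bacteria", "phylum": "Proteobacteria"},
        "b": {"kingdom": "Bacteria", "phylum": "Acidobacteriota"},
        "c": {"kingdom": "Bacteria", "phylum": "Chloroflexi"},
        "d": {"kingdom": "Bacteria", "phylum": "WeirdPhylum"},
    }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))
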