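import pandas as pd
import pytest

from phoscoreg import DatasetMeta, Registry, SiteKey
from phoscoreg.regulation import CALL_COLUMNS


def make_calls(rows):
    """rows: (dataset_id, gene, residue, position, direction[, flag])"""
    return pd.DataFrame(
        [
            {
                "dataset_id": r[0],
                "gene_symbol": r[1],
                "residue": r[2],
                "position": r[3],
                "direction": r[4],
                "flag": r[5] if len(r) > 5 else None,
            }
            for r in rows
        ],
        columns=CALL_COLUMNS,
    )


def make_registry(dataset_ids, kind="differential", studies=None, conditions=None):
    datasets = {}
    for i, ds in enumerate(dataset_ids):
        datasets[ds] = DatasetMeta(
            dataset_id=ds,
            study_id=studies[i] if studies else f"study{i + 1}",
            condition_id=conditions[i] if conditions else f"cond{i + 1}",
            dataset_kind=kind,
        )
    return Registry(datasets=datasets)


ANCHOR = SiteKey("MAPT", "S", 519)
PSOP = SiteKey("NUCKS1", "S", 214)


@pytest.fixture
def coreg_fixture():
    """Ten differential datasets: 2 UU, 1 DD, 1 UD, 2 anchor-only, 1
    psop-only, 3 with neither regulated -> a=3, b=3, c=1, d=3."""
    universe = [f"ds{i}" for i in range(1, 11)]
    rows = []
    patterns = {
        "ds1": ("U", "U"),
        "ds2": ("U", "U"),
        "ds3": ("D", "D"),
        "ds4": ("U", "D"),
        "ds5": ("U", "NR"),
        "ds6": ("D", None),   # anchor-only: psop not measured at all
        "ds7": (None, "D"),   # psop-only
        "ds8": ("NR", "NR"),
        "ds9": ("NR", None),
        "ds10": (None, None),
    }
    for ds, (da, dp) in patterns.items():
        if da is not None:
            rows.append((ds, ANCHOR.gene_symbol, ANCHOR.residue, ANCHOR.position, da))
        if dp is not None:
            rows.append((ds, PSOP.gene_symbol, PSOP.residue, PSOP.position, dp))
    return make_calls(rows), universe


S713 = SiteKey("MAPT", "S", 713)
S717 = SiteKey("MAPT", "S", 717)


@pytest.fixture
def cooccur_fixture():
    """Six datasets with pair calls (U,U),(U,U),(D,D),(U,D),(NR,U),(D,absent)
    -> nUU=2, nDD=1, nUD=1, nDU=0."""
    rows = [
        ("d1", "MAPT", "S", 713, "U"), ("d1", "MAPT", "S", 717, "U"),
        ("d2", "MAPT", "S", 713, "U"), ("d2", "MAPT", "S", 717, "U"),
        ("d3", "MAPT", "S", 713, "D"), ("d3", "MAPT", "S", 717, "D"),
        ("d4", "MAPT", "S", 713, "U"), ("d4", "MAPT", "S", 717, "D"),
        ("d5", "MAPT", "S", 713, "NR"), ("d5", "MAPT", "S", 717, "U"),
        ("d6", "MAPT", "S", 713, "D"),
    ]
    return make_calls(rows)


@pytest.fixture
def differential_tsv(tmp_path):
    """A small well-formed canonical differential table on disk."""
    path = tmp_path / "diff.tsv"
    header = (
        "dataset_id\tstudy_id\tcondition_id\tgene_symbol\tuniprot_acc\t"
        "residue\tposition\tfold_change\tp_value\tlocalization_probability\ta_score"
    )
    rows = [
        "ds1\tst1\tc1\tMAPT\tP10636\tS\t519\t1.8\t0.01\t0.99\t.",
        "ds1\tst1\tc1\tNUCKS1\t.\tS\t214\t0.5\t0.02\t0.9\t.",
        "ds1\tst1\tc1\tAHNAK\t.\tS\t5448\t1.1\t0.6\t.\t20",
    ]
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path
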