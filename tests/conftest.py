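import numpy as np
import pytest

from icessd.core_data import geometric_mean_by_species, load_table1
from icessd.ice_models import load_published_models

# log10 values of the bundled tables, used directly where a test needs the
# raw numbers rather than the loaders under test
TABLE1_UGL = [770.0, 958.0, 5200.0, 2150.0, 218000.0, 603000.0, 305000.0,
              580.0, 145.0, 1000000.0, 2610.0]
TABLE2_UGL = [724.26, 628.65, 755.41, 580.28, 279.27, 437.8, 787.86,
              61347.21, 60703.33, 61269.36, 60424.03, 79193.94, 44376.05,
              85160.74, 28786.62, 50142.3, 2161.17, 3457.14, 350.71]


@pytest.fixture(scope="session")
def table1_records():
    return load_table1()


@pytest.fixture(scope="session")
def table1_species(table1_records):
    return geometric_mean_by_species(table1_records)


@pytest.fixture(scope="session")
def table2_pairs():
    return load_published_models()


@pytest.fixture
def species_csv(tmp_path):
    """Write a minimal species table CSV and return its path."""

    def _write(rows, unit_col=True, header=None):
        cols = ["species", "genus", "family", "order", "class", "phylum",
                "endpoint", "effect", "duration_h", "concentration"]
        if unit_col:
            cols.append("unit")
        cols.append("source_ref")
        lines = [",".join(header if header is not None else cols)]
        lines += [",".join(str(v) for v in row) for row in rows]
        path = tmp_path / "table.csv"
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def make_row(species="Testus species", conc=100.0, unit="ugL", family="Testidae",
             duration=96, endpoint="LC50", effect="mortality"):
    return [species, "Testus", family, "Testiformes", "Testia", "Testica",
            endpoint, effect, duration, conc, unit, "ref"]


def rng_for(seed):
    return np.random.default_rng(seed)
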