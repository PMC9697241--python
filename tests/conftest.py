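import pandas as pd
import pytest

from phosphonet import PhosphoSite, ProteinRecord


def make_record(
    accession="P1",
    species="human",
    length=500,
    mass=55_000.0,
    n_sites=0,
    hid=None,
):
    """A protein record with ``n_sites`` sites at positions 1..n_sites."""
    sites = tuple(PhosphoSite(p + 1, "S") for p in range(n_sites))
    return ProteinRecord(
        accession=accession,
        species=species,
        length=length,
        mass=mass,
        phospho_sites=sites,
        homology_group=hid,
    )


@pytest.fixture
def tsv(tmp_path):
    """Write a DataFrame (or rows + columns) as a TSV and return the path."""

    def _write(rows, columns=None, name="table.tsv"):
        df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(
            rows, columns=columns
        )
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write
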