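import pytest

from seabarcode.seqio import Alignment, SequenceRecord
from seabarcode.simdata import (LocusSpec, SimulationConfig, simulate_dataset)


def make_alignment(rows, locus="test", **meta_per_id):
    """rows: {id: seq} (insertion-ordered)."""
    records = []
    for rid, seq in rows.items():
        meta = meta_per_id.get(rid, {}) if meta_per_id else {}
        records.append(SequenceRecord(id=rid, seq=seq, locus=locus, **meta))
    return Alignment(locus=locus, records=records)


@pytest.fixture(scope="session")
def small_truth():
    """A compact simulated dataset: 2 families, 3 genera, 4 species,
    2 individuals each (8 tips), one fast locus with strong signal."""
    cfg = SimulationConfig(
        n_families=2, genera_per_family=(2, 1),
        species_per_genus=(1, 1, 2), individuals_per_species=2,
        loci=(LocusSpec("fast", length=500, rate_multiplier=6.0),),
        seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_truth():
    """The default seagrass-like three-locus dataset (30 tips)."""
    return simulate_dataset(SimulationConfig(seed=7))
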