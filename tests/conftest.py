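import numpy as np
import pytest

from gcfkit.families import GcfPartition, categorize_gcfs
from gcfkit.model import BgcRecord, DomainCount
from gcfkit.simulate import SimulationParams, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic genus (4 clades x 5 strains + 2 outliers),
    seed 42.  Session-scoped: generation is deterministic."""
    return generate_dataset(SimulationParams(seed=42))


@pytest.fixture(scope="session")
def truth_partition(default_dataset):
    """GcfPartition built directly from the planted family labels."""
    _, truth = default_dataset
    return partition_from_truth(truth)


def partition_from_truth(truth) -> GcfPartition:
    fams: dict[str, list[str]] = {}
    for bid, fam in truth.gcf_of.items():
        fams.setdefault(fam, []).append(bid)
    part = GcfPartition(
        family_of=dict(truth.gcf_of),
        members={f: sorted(v) for f, v in fams.items()},
        strains={f: {b.split("__")[0] for b in v} for f, v in fams.items()},
        consensus_class={f: "PKS" for f in fams},
    )
    return categorize_gcfs(part)


def random_bgc(rng: np.random.Generator, bgc_id: str, alphabet: int = 30,
               max_types: int = 8, allow_empty: bool = False) -> BgcRecord:
    """Random domain-content-only BGC for metric property tests."""
    lo = 0 if allow_empty else 1
    n = int(rng.integers(lo, max_types + 1))
    accs = rng.choice(alphabet, size=n, replace=False)
    domains = [
        DomainCount(f"PF{int(a):05d}", int(rng.integers(1, 5))) for a in accs
    ]
    return BgcRecord(
        bgc_id=bgc_id, genome_id="g", bgc_class="PKS",
        start=0, end=1000, domains=domains,
    )
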