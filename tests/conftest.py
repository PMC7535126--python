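import numpy as np
import pytest

from chcadd import synthetic


@pytest.fixture(scope="session")
def default_world():
    """One synthetic world at the package's default study conditions."""
    return synthetic.make_world(seed=11)


@pytest.fixture(scope="session")
def neutral_world():
    """Same world with constraint suppression disabled (null conditions)."""
    cfg = synthetic.WorldConfig(suppression_factor=1.0, daf_gamma=0.0)
    return synthetic.make_world(cfg, seed=11)


def split_snps_by_region(world):
    """(constrained, neutral) lists of (chrom, pos) SNPs of a world."""
    starts = np.array([r.start for r in world.constrained_regions])
    ends = np.array([r.end for r in world.constrained_regions])

    def in_constrained(pos0):
        i = np.searchsorted(starts, pos0, side="right") - 1
        return i >= 0 and pos0 < ends[i]

    cons, neut = [], []
    for rec in world.population:
        (cons if in_constrained(rec.pos - 1) else neut).append(
            (rec.chrom, rec.pos))
    return cons, neut
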