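import numpy as np
import pytest

from tagglyco import build_default_list, default_registry
from tagglyco.residues import BOA_SODIUM


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def label():
    return BOA_SODIUM


@pytest.fixture(scope="session")
def glycan_list(registry):
    """Full default candidate list (SALSA-expanded, NeuGc included)."""
    return build_default_list(registry)


@pytest.fixture(scope="session")
def human_list(registry):
    """Default list with NeuGc-bearing entries removed (human serum)."""
    return build_default_list(registry, exclude_neugc=True)


def pick_isolated_entries(lst, n, min_gap, lo=1300.0, hi=3000.0):
    """Entries whose theoretical mass has no list neighbour within min_gap.

    Used to build synthetic panels where annotation must be unambiguous.
    """
    masses = np.array(sorted(e.theoretical_mz for e in lst))
    out = []
    for e in sorted(lst, key=lambda e: e.theoretical_mz):
        if not lo <= e.theoretical_mz <= hi:
            continue
        i = np.searchsorted(masses, e.theoretical_mz)
        neighbours = [masses[j] for j in (i - 1, i + 1) if 0 <= j < len(masses)]
        if all(abs(e.theoretical_mz - m) > min_gap for m in neighbours):
            if out and abs(out[-1].theoretical_mz - e.theoretical_mz) < 2 * min_gap:
                continue
            out.append(e)
        if len(out) == n:
            return out
    raise RuntimeError(f"only found {len(out)} isolated entries")
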