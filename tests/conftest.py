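import numpy as np
import pandas as pd
import pytest

from rohdel.simdata import GroupSpec, SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_sim():
    """Default two-group population on a 20 Mb chromosome."""
    return simulate_population(SimConfig(seed=3))


@pytest.fixture(scope="session")
def tiny_sim():
    """A minimal population for fast file-format round trips."""
    cfg = SimConfig(
        seed=11,
        chrom_lengths=(("chr1", 2_000_000), ("chr2", 1_000_000)),
        groups=(
            GroupSpec("lf", 3, roh_rate_per_mb=0.2, roh_length_log_mean=np.log(3e5)),
            GroupSpec("nb", 3, roh_rate_per_mb=0.5, roh_length_log_mean=np.log(4e5)),
        ),
        n_sites_per_class={"synonymous": 300, "tolerated": 100, "deleterious": 50, "lof": 20},
        missing_rate=0.05,
    )
    return simulate_population(cfg)


def windows_frame(het, usable, bin_size=10_000, chrom="chr1"):
    """Build a window track from per-bin het values and usable flags."""
    het = np.asarray(het, dtype=float)
    usable = np.asarray(usable, dtype=bool)
    n = het.size
    starts = np.arange(n) * bin_size
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + bin_size,
            "n_het": 0,
            "n_wellcovered": np.where(usable, bin_size, 0),
            "het_corrected": np.where(usable, het, np.nan),
            "usable": usable,
        }
    )
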