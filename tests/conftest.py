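import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mixploid.containers import GenotypeMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def matrix_factory():
    """Build a GenotypeMatrix from a dosage array with optional annotations."""

    def build(
        dosage,
        ploidy,
        *,
        positions=None,
        chrom=None,
        ref=None,
        alt=None,
        qd=None,
        fs=None,
        mq=None,
        groups=None,
    ):
        dosage = np.asarray(dosage)
        n, L = dosage.shape
        sites = pd.DataFrame(
            {
                "chrom": chrom if chrom is not None else ["chr1"] * L,
                "pos": positions if positions is not None else np.arange(1, L + 1),
                "ref": ref if ref is not None else ["A"] * L,
                "alt": alt if alt is not None else ["G"] * L,
                "qd": qd if qd is not None else np.full(L, 20.0),
                "fs": fs if fs is not None else np.full(L, 5.0),
                "mq": mq if mq is not None else np.full(L, 50.0),
            }
        )
        return GenotypeMatrix(
            samples=[f"s{i}" for i in range(n)],
            ploidy=np.asarray(ploidy),
            dosage=dosage,
            sites=sites,
            groups=groups or {},
        )

    return build
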