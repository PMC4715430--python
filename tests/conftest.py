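import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20160114)


@pytest.fixture
def five_locale_table(tmp_path):
    """Two western (K, C) and three eastern (L, A, T) locales, two pitchers each."""
    rows = []
    for locale, region in [("K", "west"), ("C", "west"), ("L", "east"), ("A", "east"), ("T", "east")]:
        for k in range(2):
            rows.append(
                {
                    "sample_id": f"{locale}{k}",
                    "locale": locale,
                    "region": region,
                    "month": "June" if k == 0 else "August",
                }
            )
    path = tmp_path / "samples.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def random_seq(rng, length=275):
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(rng, seq, n_sub):
    """Substitute exactly n_sub distinct sites."""
    out = list(seq)
    for site in rng.choice(len(seq), size=n_sub, replace=False):
        out[site] = rng.choice([b for b in "ACGT" if b != out[site]])
    return "".join(out)
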