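import numpy as np
import pandas as pd
import pytest

from trichostudy.scoring import CorrectnessMatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


def make_matrix(rows, groups, cases=None):
    """Small CorrectnessMatrix from a dict {rater: [0/1/None, ...]}."""
    raters = list(rows)
    n = len(next(iter(rows.values())))
    cases = cases or [f"case_{i + 1}" for i in range(n)]
    values = pd.DataFrame(
        [[np.nan if v is None else float(v) for v in rows[r]] for r in raters],
        index=raters, columns=cases)
    return CorrectnessMatrix(values, pd.Series(groups))


@pytest.fixture(scope="session")
def small_scalp():
    from trichostudy.synthetic import ImageSpec, generate_scalp_image
    spec = ImageSpec(height=96, width=96, n_hairs=6, n_follicular_dots=3)
    img, structures = generate_scalp_image(spec, seed=11)
    return spec, img, structures
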