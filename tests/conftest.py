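import numpy as np
import pandas as pd
import pytest


def make_cells(intensities, spec, cell_class="tumour", patient_id=1, core_id="c1"):
    """Cell table whose optical densities bin exactly to the given intensities."""
    bins = np.array(spec.od_bins)
    width = bins[-1] - bins[-2] if bins.size > 1 else bins[0]
    edges = np.concatenate([[0.0], bins, [bins[-1] + width]])
    mids = (edges[:-1] + edges[1:]) / 2
    od = mids[np.asarray(intensities, int)]
    n = len(od)
    classes = [cell_class] * n if isinstance(cell_class, str) else list(cell_class)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "core_id": core_id,
            "cell_class": classes,
            "od_nuclear": od,
            "od_cytoplasm": od,
            "od_perinuclear": od,
            "od_cell": od,
        }
    )


@pytest.fixture
def panel():
    from ihcsig import default_panel

    return default_panel()
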