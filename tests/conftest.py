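import numpy as np
import pandas as pd
import pytest

from pafkit.estimation import CaseControlDataset, ExposureSpec
from pafkit import frame_to_results, stroke_risk_factors

# printed approximate-PAF column (percent) of the published stroke
# risk-factor table, in the table's own (descending) order
PUBLISHED_APPROX_PAF_PCT = [51.8, 41.9, 28.6, 25.3, 19.7, 11.5, 5.7, 5.2, 4.3, 1.9]


@pytest.fixture(scope="session")
def stroke_summary():
    return stroke_risk_factors()


@pytest.fixture(scope="session")
def stroke_results(stroke_summary):
    return frame_to_results(stroke_summary)


@pytest.fixture()
def toy_2x2():
    """30/70 exposed/unexposed cases, 10/90 controls: log-OR = ln(27/7)."""
    df = pd.DataFrame(
        {
            "y": [1] * 100 + [0] * 100,
            "a": [1] * 30 + [0] * 70 + [1] * 10 + [0] * 90,
        }
    )
    return CaseControlDataset.from_dataframe(
        df, "y", {"a": ExposureSpec("binary", reference=0)}
    )


def make_2x2(case_exposed, case_unexposed, control_exposed, control_unexposed):
    df = pd.DataFrame(
        {
            "y": [1] * (case_exposed + case_unexposed)
            + [0] * (control_exposed + control_unexposed),
            "a": [1] * case_exposed
            + [0] * case_unexposed
            + [1] * control_exposed
            + [0] * control_unexposed,
        }
    )
    return CaseControlDataset.from_dataframe(
        df, "y", {"a": ExposureSpec("binary", reference=0)}
    )
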