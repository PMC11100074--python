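import pandas as pd
import pytest

import ecrisk


@pytest.fixture(scope="session")
def panel():
    return ecrisk.default_panel()


@pytest.fixture(scope="session")
def cohort(panel):
    """A 500/500 synthetic cohort generated under the study's effect
    sizes, with the wGRS column attached."""
    spec = ecrisk.PopulationSpec(snps=panel, n_cases=500, n_controls=500, seed=7)
    df = ecrisk.generate_case_control(spec)
    df["wgrs"] = ecrisk.add_wgrs(df, panel)
    return df


@pytest.fixture(scope="session")
def printed_counts_cohort():
    """A subject table whose exposure margins equal the published
    baseline table exactly (222/278 vs 173/327 smoking, 194/306 vs
    148/352 drinking, 78/422 vs 10/490 family history)."""

    def arm(n, status, smoking_yes, drinking_yes, fh_yes):
        return pd.DataFrame(
            {
                "status": status,
                "age": 60.0,
                "sex": ["male"] * n,
                "smoking": [1] * smoking_yes + [0] * (n - smoking_yes),
                "drinking": [1] * drinking_yes + [0] * (n - drinking_yes),
                "family_history": [1] * fh_yes + [0] * (n - fh_yes),
            }
        )

    df = pd.concat(
        [arm(500, 1, 222, 194, 78), arm(500, 0, 173, 148, 10)], ignore_index=True
    )
    df.insert(0, "id", [f"S{i}" for i in range(len(df))])
    return df
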