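import numpy as np
import pytest

from saccadapt import model, synthetic_data as sd


@pytest.fixture(scope="session")
def design_plus():
    return sd.build_design("small_target", "discriminate_1st", "plus")


@pytest.fixture(scope="session")
def design_minus():
    return sd.build_design("small_target", "discriminate_1st", "minus")


def literal_recursion(w, r, d, init, loc):
    """Independent brute-force oracle: the update equations, trial by trial.

    Written deliberately as a plain per-trial loop over the three update
    equations, without any of the algebraic simplifications used by the
    implementation.
    """
    loc = list(loc)
    hor = [float(init)]
    strategic = [float(init)]
    gradual = [float(init)]
    for n in range(1, len(loc)):
        s_n = hor[n - 1] - (hor[n - 1] - loc[n - 1] * d)
        g_n = hor[n - 1] - r * (hor[n - 1] - loc[n - 1] * d)
        strategic.append(s_n)
        gradual.append(g_n)
        hor.append(w * s_n + (1 - w) * g_n)
    return np.array(strategic), np.array(gradual), np.array(hor)


@pytest.fixture(scope="session")
def noiseless_truth():
    return sd.GroundTruth(
        params_true=model.ModelParams(w=0.6, r=0.2, d=1, init=0.0), noise_sd=0.0
    )
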