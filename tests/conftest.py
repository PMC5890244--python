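import numpy as np
import pytest

import snifflet as sn
from snifflet.model import FitConfig


@pytest.fixture(scope="session")
def sniff_train_300():
    return sn.sample_sniff_train(300, seed=101)


@pytest.fixture(scope="session")
def coarse_config():
    return FitConfig.coarse()


@pytest.fixture(scope="session")
def stereotyped_fit_pair(sniff_train_300, coarse_config):
    """A (truth, fit) pair for a stereotyped early-excitation cell."""
    psi_true = sn.make_truth_snifflet("stereotyped", seed=7)
    spikes = sn.sample_spike_train(psi_true, sniff_train_300, seed=8)
    fit = sn.fit_snifflet(spikes, sniff_train_300, coarse_config)
    return psi_true, fit


def make_train(onsets, d_inh, d_total=None):
    onsets = np.asarray(onsets, float)
    d_inh = np.broadcast_to(np.asarray(d_inh, float), onsets.shape)
    if d_total is None:
        ends = np.append(onsets[1:], onsets[-1] + 0.4)
    else:
        ends = onsets + np.broadcast_to(np.asarray(d_total, float), onsets.shape)
    return sn.SniffTrain.from_arrays(onsets, onsets + d_inh, ends)
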