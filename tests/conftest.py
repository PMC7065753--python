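from datetime import datetime, timedelta

import numpy as np
import pytest

from camtrap_niche.records import Detection, StationDeployment


@pytest.fixture
def rng():
    return np.random.default_rng(20170301)


def make_detections(minutes, species="leopard", station="ST01",
                    start=datetime(2017, 3, 1, 6, 0)):
    """Detections at the given minute offsets from a fixed start."""
    return [
        Detection(species=species, station_id=station,
                  timestamp=start + timedelta(minutes=float(m)))
        for m in minutes
    ]


@pytest.fixture
def four_stations():
    return [
        StationDeployment("ST01", "MoistMixed", 10.0),
        StationDeployment("ST02", "TeakAcaciaZizyphus", 20.0),
        StationDeployment("ST03", "Mixed", 10.0),
        StationDeployment("ST04", "Thorn", 20.0),
    ]
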