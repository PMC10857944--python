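import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ctstia as ct

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_survey(deployments_rows, detections_rows):
    """Build a SurveyDataset from (station, start, end, land_cover) and
    (station, species, timestamp) tuples of strings."""
    dep = pd.DataFrame(
        deployments_rows, columns=["station_id", "start", "end", "land_cover"]
    )
    det = pd.DataFrame(
        detections_rows, columns=["station_id", "species", "timestamp"]
    )
    return ct.SurveyDataset(deployments=dep, detections=det)


@pytest.fixture
def tiny_survey():
    """Two stations (28 d + 27 d = 55 trap-days), a few detections."""
    return make_survey(
        [
            ("A", "2022-05-03T00:00:00", "2022-05-31T00:00:00", "woodland"),
            ("B", "2022-05-03T00:00:00", "2022-05-30T00:00:00", "grassland"),
        ],
        [
            ("A", "sika_deer", "2022-05-10T06:00:00"),
            ("A", "sika_deer", "2022-05-10T06:29:00"),
            ("A", "sika_deer", "2022-05-10T07:01:00"),
            ("A", "human", "2022-05-10T13:00:00"),
            ("B", "roe_deer", "2022-05-12T19:30:00"),
        ],
    )


@pytest.fixture(scope="session")
def preset_run():
    """One simulated preset survey with contacts and human rates."""
    dataset, truth = ct.simulate_survey(ct.preset_paper_like(), seed=7)
    contacts = ct.filter_independent(dataset)
    human_rates = ct.human_detection_rates(contacts, dataset)
    return dataset, truth, contacts, human_rates


def minute_stream(minutes, station="A", species="sika_deer", base="2022-05-10T00:00:00"):
    """Detections at the given minute marks at one station."""
    t0 = pd.Timestamp(base)
    rows = [(station, species, str(t0 + pd.Timedelta(minutes=float(m)))) for m in minutes]
    dep = [(station, "2022-05-03T00:00:00", "2022-05-31T00:00:00", "woodland")]
    return make_survey(dep, rows)
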