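"""The 32-channel 10-10 montage and the eight sensorimotor electrode configurations.

The eight configurations cover the motor, premotor and medial areas in
left/right/midline subsets; classification is always run on one of them
after common-average referencing over the full montage.  Memberships can
be overridden from a ``montages.tsv`` file (``config_id``, ``name``,
comma-separated channel labels).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .windows import Epoch

#: Full 32-electrode 10-10 montage of the recording system.
MONTAGE_32 = [
    "P7", "P4", "CZ", "PZ", "P3", "P8", "O1", "O2",
    "C2", "F8", "C4", "F4", "FP2", "FZ", "C3", "F3",
    "FP1", "C1", "F7", "OZ", "PO4", "FC6", "FC2", "AF4",
    "CP6", "CP2", "CP1", "CP5", "FC1", "FC5", "AF3", "PO3",
]


@dataclass(frozen=True)
class ElectrodeConfiguration:
    """One of the eight studied channel subsets (id 1-8)."""

    config_id: int
    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("electrode configuration must be non-empty")
        unknown = [c for c in self.channels if c not in MONTAGE_32]
        if unknown:
            raise ValidationError(f"channels not in the 32-electrode montage: {unknown}")

    @property
    def n_electrodes(self) -> int:
        return len(self.channels)


def _ec(cid: int, name: str, channels: str) -> ElectrodeConfiguration:
    return ElectrodeConfiguration(cid, name, tuple(channels.split(",")))


#: Default memberships for configurations 1-8.  1: motor+premotor; 2: motor;
#: 3: premotor; 4/6: left/right motor+premotor; 5/7: left/right plus medial;
#: 8: reduced motor+premotor.
DEFAULT_CONFIGS: dict[int, ElectrodeConfiguration] = {
    1: _ec(1, "motor+premotor", "FC5,FC1,FC2,FC6,C3,C1,CZ,C2,C4"),
    2: _ec(2, "motor", "C3,C1,CZ,C2,C4"),
    3: _ec(3, "premotor", "FC5,FC1,FC2,FC6"),
    4: _ec(4, "left motor+premotor", "FC5,FC1,C3,C1"),
    5: _ec(5, "left+medial", "FC5,FC1,C3,C1,CZ,CP1"),
    6: _ec(6, "right motor+premotor", "FC2,FC6,C2,C4"),
    7: _ec(7, "right+medial", "FC2,FC6,C2,C4,CZ,CP2"),
    8: _ec(8, "reduced motor+premotor", "FC1,FC2,C3,CZ,C4"),
}

#: Electrode counts used by the minimal-electrode tie-break.
DEFAULT_CONFIG_SIZES: dict[int, int] = {
    cid: cfg.n_electrodes for cid, cfg in DEFAULT_CONFIGS.items()
}


def get_configuration(config_id: int, configs: dict[int, ElectrodeConfiguration] | None = None) -> ElectrodeConfiguration:
    configs = configs if configs is not None else DEFAULT_CONFIGS
    try:
        return configs[config_id]
    except KeyError:
        raise ValidationError(f"unknown electrode configuration id {config_id}") from None


def select_channels(epoch: Epoch, config: ElectrodeConfiguration) -> Epoch:
    """Restrict an epoch to the configuration's channels (order preserved).

    Raises :class:`ValidationError` naming the first missing channel.
    """
    index = {name: i for i, name in enumerate(epoch.channel_names)}
    rows = []
    for ch in config.channels:
        if ch not in index:
            raise ValidationError(f"epoch is missing channel {ch} required by E.C. {config.config_id}")
        rows.append(index[ch])
    return Epoch(
        start_time=epoch.start_time,
        data=epoch.data[rows, :],
        channel_names=list(config.channels),
        sampling_rate=epoch.sampling_rate,
    )


def load_montages(path: str | Path) -> dict[int, ElectrodeConfiguration]:
    """Load configurations from a montages.tsv file."""
    df = pd.read_csv(path, sep="\t")
    configs = {}
    for _, row in df.iterrows():
        cid = int(row["config_id"])
        if cid in configs:
            raise ValidationError(f"duplicate configuration id {cid}")
        configs[cid] = _ec(cid, str(row["name"]), str(row["channels"]).replace(" ", ""))
    return configs


def write_montages(configs: dict[int, ElectrodeConfiguration], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "config_id": [c.config_id for c in configs.values()],
            "name": [c.name for c in configs.values()],
            "channels": [",".join(c.channels) for c in configs.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)
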