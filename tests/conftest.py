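import numpy as np
import pytest

from guildflux.reactor_sim import (
    ARCHAEAL_CH4_KS_MMOL,
    BACTERIAL_CH4_KS_MMOL,
    GuildKinetics,
    KineticParams,
)
from guildflux.stoichiometry import ReactorConfig, guild_reactions


@pytest.fixture(scope="session")
def registry():
    return guild_reactions()


@pytest.fixture
def anammox(registry):
    return registry["anammox"]


@pytest.fixture
def balanced_feed_config():
    """Ammonium + nitrite feed at the anammox-demand molar ratio 1.32,
    total N 500 mg N/L, HRT 1 d."""
    nh4 = 500.0 / 2.32
    return ReactorConfig(
        hrt_days=1.0, influent={"NH4": nh4, "NO2": 500.0 - nh4, "NO3": 0.0}
    )


def guild_params(v_an, v_db, v_da, n_ks=1.0):
    return KineticParams(
        anammox=GuildKinetics(v_an, {"NH4": n_ks, "NO2": n_ks}),
        ndamo_bacteria=GuildKinetics(v_db, {"NO2": n_ks, "CH4": BACTERIAL_CH4_KS_MMOL}),
        ndamo_archaea=GuildKinetics(v_da, {"NO3": n_ks, "CH4": ARCHAEAL_CH4_KS_MMOL}),
    )


@pytest.fixture
def make_guild_params():
    return guild_params
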