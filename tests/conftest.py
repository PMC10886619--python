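import pytest

from phagedrop import SpotObservation, SpotStatus, table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


def make_spot(count=None, status=SpotStatus.COUNTED, exponent=0, rep=1,
              volume=5.0, phage="P1", strain="S1", partner=None):
    return SpotObservation(
        phage_id=phage, strain_id=strain, dilution_exponent=exponent,
        replicate_index=rep, drop_volume_ul=volume, status=status,
        plaque_count=count, merge_partner=partner)


def make_series(counts_by_exponent, volume=5.0, phage="P1", strain="S1"):
    """Build a triplicate series from {exponent: spec} where spec is a list
    of per-replicate entries: an int/float count (0 -> intact lawn) or one
    of the status strings 'confluent'/'no_drop'/'no_lysis'."""
    spots = []
    for exponent, entries in counts_by_exponent.items():
        for rep, entry in enumerate(entries, start=1):
            if isinstance(entry, str):
                spots.append(make_spot(None, SpotStatus(entry), exponent, rep,
                                       volume, phage, strain))
            elif entry == 0:
                spots.append(make_spot(None, SpotStatus.NO_LYSIS, exponent, rep,
                                       volume, phage, strain))
            else:
                spots.append(make_spot(float(entry), SpotStatus.COUNTED,
                                       exponent, rep, volume, phage, strain))
    return spots
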