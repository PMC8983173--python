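import pytest

from hlae_typing import AlleleDB, AlleleRecord, SiteSpec
from hlae_typing.synthetic import hrm_references, toy_db


@pytest.fixture(scope="session")
def db():
    """Packaged synthetic toy database: 4 alleles, 400 nt, NT-26 at column 133."""
    return toy_db()


@pytest.fixture(scope="session")
def site(db):
    return db.site("NT-26")


def make_db(seqs: dict[str, str], site_index: int = 2, ref: str = "G", alt: str = "T"):
    """Tiny in-memory database for hand-checkable examples."""
    return AlleleDB(
        records={aid: AlleleRecord(aid, s) for aid, s in seqs.items()},
        site_map={"NT-26": SiteSpec("NT-26", site_index, ref, alt)},
    )


@pytest.fixture(scope="session")
def tiny_db():
    """Four 4-mers with the site at column 2; one T allele, two identical alleles."""
    return make_db(
        {
            "E_G_PROMOTER": "ACGT",
            "E_T_PROMOTER": "ACTT",
            "E_G_VAR": "TCGT",
            "E_G_VAR_DUP": "TCGT",  # identical to E_G_VAR within the amplicon
        }
    )


@pytest.fixture(scope="session")
def refs():
    return hrm_references()
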