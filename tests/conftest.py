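import numpy as np
import pytest

from cohortqc import (EvidenceFeatures, GenomicInterval, Pedigree,
                      PedigreeSample, SimulationConfig, SVRecord,
                      simulate_cohort)


def make_sv(chrom="chr1", start=1000, end=None, svtype="DEL", length=None,
            record_id="sv1", source="callerA", genotypes=None, sr=None,
            boost=None):
    """Terse SVRecord constructor for tests."""
    if svtype == "INS":
        end = start
        length = length or 300
    else:
        length = length or 100
        end = end if end is not None else start + length
    genotypes = genotypes or [(0, 1)]
    n = len(genotypes)
    ev = [EvidenceFeatures(sr_count=(sr[i] if sr else 0)) for i in range(n)]
    rec = SVRecord(interval=GenomicInterval(chrom, start, end), svtype=svtype,
                   length=length, source=source, record_id=record_id,
                   genotypes=genotypes, evidence=ev)
    if boost is not None:
        rec.boost_scores = list(boost)
    return rec


def make_pedigree(n_trios=1, n_unrelated=0):
    samples = {}
    for t in range(n_trios):
        f, m, c = f"F{t}", f"M{t}", f"C{t}"
        samples[f] = PedigreeSample(f, None, None, "male")
        samples[m] = PedigreeSample(m, None, None, "female")
        samples[c] = PedigreeSample(c, f, m, "female")
    for u in range(n_unrelated):
        samples[f"U{u}"] = PedigreeSample(f"U{u}", None, None, "male")
    return Pedigree(samples)


@pytest.fixture(scope="session")
def small_cohort():
    """Small deterministic synthetic cohort shared across tests."""
    config = SimulationConfig(seed=7, n_trios=12, n_unrelated=16,
                              n_small_sites=400, n_sv_sites=120)
    return simulate_cohort(config)
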