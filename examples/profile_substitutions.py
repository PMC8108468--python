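"""Call MWS-like substitutions in a study-shaped grouped opsin set.

Generates 102 Baikal LWS, 6 European LWS and 4 European MWS sequences
with 32 planted MWS-like substitutions, aligns them with the bovine
rhodopsin numbering reference, calls the events and compares the joint
carriage of the top three with the independence expectation.
"""

from opsinminer import fixtures as fx
from opsinminer import profiler as pf

seqs, truth = fx.make_grouped_set(seed=1)
ga = pf.build_grouped_alignment(seqs)
events = pf.call_mws_like(ga)
counts, n_over = pf.occurrence_spectrum(events, threshold=10)

print(f"called {len(events)} MWS-like substitutions "
      f"({n_over} occur more than 10 times); top counts {counts[:5]}")
for e in events:
    if e.is_tuning_site:
        print(f"  spectral tuning site hit: {e.residue}{e.bovine_pos} "
              f"(count {e.count})")
print(pf.cooccurrence(ga, events[:3]).report())

# Carrier counts of 48/30/19 over 102 sequences predict only 2.6% joint
# carriage under independence; the planted (and recovered) 11/102 is
# about four times that, the signature of a shared history rather than
# independent recurrent substitutions.
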