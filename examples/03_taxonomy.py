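"""Consensus taxonomy against a primer-trimmed reference database.

Trims full-length references to the amplified region using the PCR
primers as a guide, searches an OTU at six nested identity thresholds
(100/98/97/95/92/90%) and resolves the deepest concordant label.
"""

import pairtax as pt
from pairtax.iupac import PRIMER_515F, PRIMER_806R, reverse_complement

refs = pt.synth_references(17, 17, seed=42)
db, n_rejected = pt.trim_database(refs, PRIMER_515F, PRIMER_806R, read_len=70)
print(f"trimmed references: {len(db)} (rejected: {n_rejected})")

# an OTU identical to one reference, and one with two substitutions
ref = db[0]
clean = pt.OTURecord("otu_clean", ref.fwd_frag, reverse_complement(ref.rev_frag), 100)
noisy_fwd = ("G" if ref.fwd_frag[0] != "G" else "T") + ref.fwd_frag[1:]
noisy_rev = reverse_complement(ref.rev_frag)
noisy_rev = ("G" if noisy_rev[0] != "G" else "T") + noisy_rev[1:]
noisy = pt.OTURecord("otu_noisy", noisy_fwd, noisy_rev, 100)

for otu in (clean, noisy):
    profile = pt.search_hits(otu, db)
    top = profile.top_level()
    asg = pt.consensus_label(profile, otu.otu_id)
    print(
        f"{otu.otu_id}: top hit level {top:.2f}, rank {asg.assigned_rank}, "
        f"label {asg.lineage[5] or asg.lineage[4]}, "
        f"specificity {asg.specificity:.1f}% over {asg.supporting_hits} hit(s)"
    )
# The clean OTU hits its reference at the 100% level; two substitutions
# (combined identity 138/140) drop it to the 98% level but the genus
# call is unchanged because every populated level agrees.
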