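"""Annotate off-target sites by TSS proximity (500 bp, inclusive).

Places three gene TSSs at 0, 500 and 501 bp from a site to show the
inclusive window boundary, then lists the distinct proximal genes.
"""

import crispri_specificity as cs

site = cs.OffTargetSite("chr1", 1000, "+", "sg1", end=1020)
tss = [
    cs.TSSRecord("INSIDE", "chr1", 1010),      # inside the interval -> d = 0
    cs.TSSRecord("AT500", "chr1", 1019 + 500),  # exactly 500 bp -> proximal
    cs.TSSRecord("AT501", "chr1", 1019 + 501),  # one base further -> not
]
hits = cs.annotate_proximal([site], tss, window=500)
for h in hits:
    print(f"{h.gene}: distance {h.distance} bp from site "
          f"{h.site.chromosome}:{h.site.start}-{h.site.end}")
print("proximal genes:", sorted(cs.proximal_genes(hits)))
# Only genes whose TSS lies within 500 bp (inclusive) of any base of the
# site count as "proximal to a potential off-target binding site".
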