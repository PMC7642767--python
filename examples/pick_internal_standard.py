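"""Choose an internal standard for a target genome size.

Each standard resolves genomes inside a fixed ratio band around its own
1C value (defaults calibrated so the Locusta migratoria male standard
covers 2-20 Gb).  A standard whose 2C peak would overlap the sample's
is flagged so an alternative can be co-prepared instead.
"""

from cvalkit import standards

for target_pg in (18.64, 6.5):
    print(f"target genome {target_pg} pg ({target_pg * 978:,.0f} Mb):")
    for rec in standards.select_standards(target_pg):
        flag = f"  <- {rec.note}" if rec.note else ""
        print(f"  {rec.standard.name:24s} 1C={rec.standard.one_c:6.3f} pg  "
              f"range {rec.lo_mb:7,.0f}-{rec.hi_mb:8,.0f} Mb{flag}")
    print()
# 18.64 pg (the largest genome in the packaged study tables) is covered
# only by L. migratoria; a 6.5 pg genome sits too close to that
# standard's own 6.20 pg, so it is flagged and P. americana ranks first.
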