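# Study-fixture transcription notes

`src/sutura/data/study_contacts.tsv` transcribes the narrative bone-by-bone
contact descriptions of the four study skulls.  Every row traces to the
descriptive section of one of the two bones it names, for the taxon it
names; this file records the conventions applied and the places where
the narrative required a judgement call.

## Conventions

1. **Relation words.**  An explicit *overlaps / underlies / covers /
   lies on / clasps / is clasped by* verb determines the spatial code
   (`o`/`u`, `c`/`cb`), taking precedence over accompanying adjectives.
   With no direction verb, "vertically transverse" → `t`; "parallel",
   "blunt", "butting", or a bare "meets/contacts" → `p`.
2. **Depth words.**  smooth / blunt / loose → `s`; faintly or slightly
   interfingering → `if`; moderately interfingering (and unqualified
   "interfingering") → `im`; strongly interfingering / strongly
   serrated → `is`; no depth statement (typical of the fossil) → `?`.
3. **Segments.**  When a suture is described part by part
   (anterior/middle/posterior, or medial/lateral along the course), each
   part with a distinct (relation, depth) becomes a segment, listed in
   the order narrated; adjacent identical segments are merged.
4. **Statuses.**  "does not contact" → `absent`; "cannot be determined /
   not able to observe" → `unknown`; a bone absent in a taxon (nasal and
   epipterygoid in the living species, the parasphenoid where absent)
   makes its pairs `absent`.
5. **Not coded.**  Midline contacts of a bone with its antimere (outside
   the pair model); the columella (no sutured contact described);
   pairs a taxon's description never mentions (left unscored, so they
   drop out of any comparison involving that taxon).

## Resolved disagreements between the two bones' sections

Where the two bones' own accounts of the same suture conflict, the row
follows the section with the explicit direction verb, or the more
detailed account; the main cases:

* fossil jugal–postorbital: each section says it clasps the other;
  followed the postorbital section (postorbital clasps jugal).
* fossil jugal–maxilla depth: "presumably moderately" (jugal section)
  over "slightly" (maxilla section).
* fossil pterygoid–quadrate: clasping, faintly interfingering
  (pterygoid section) over "somewhat parallel" (quadrate section).
* hawksbill frontal–parietal: the frontal section's transverse +
  clasped-by sequence over the parietal section's "underlies".
* leatherback prootic–supraoccipital: the supraoccipital section's
  overlap over the prootic section's "parallel, mostly loose".
* leatherback opisthotic–supraoccipital: the supraoccipital section's
  direction (supraoccipital overlaps) over the opisthotic section's
  "parallel".
* snapping-turtle frontal–prefrontal: prefrontal section (prefrontal
  clasps frontal) over frontal section (frontal clasps prefrontal).
* snapping-turtle parietal–postorbital: parietal section (parietal
  overlaps) over the postorbital section's "blunt, strongly
  interfingering".
* snapping-turtle squamosal–quadratojugal: quadratojugal section
  (clasps, faintly interfingering) over the squamosal section's
  "predominantly parallel".
* snapping-turtle basioccipital–pterygoid: the basioccipital section's
  two-part overlap sequence over the pterygoid section's "clasped".

Sutures the text calls "fused" (snapping-turtle
basioccipital–exoccipital) keep the stated direction with depth `?`.
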