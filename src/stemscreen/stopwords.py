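"""A fixed, versioned English stop-word snapshot.

Shipped with the package (rather than pulled from an NLP dependency) so that
cluster titles are reproducible across environments. ``EXTRA_STOPWORDS``
holds the gene-set-name noise words (database prefixes and direction tags)
that are stripped in addition to ordinary English stop-words.
"""

ENGLISH_STOPWORDS = frozenset("""
a about above after again against all am an and any are as at
be because been before being below between both but by
can cannot could
did do does doing down during
each
few for from further
had has have having he her here hers herself him himself his how
i if in into is it its itself
just
me more most my myself
no nor not now
of off on once only or other our ours ourselves out over own
same she should so some such
than that the their theirs them themselves then there these they this those
through to too
under until
very
was we were what when where which while who whom why will with would
you your yours yourself yourselves
""".split())

# gene-set-name noise: database prefixes and direction/shape tags
EXTRA_STOPWORDS = frozenset({"reactome", "kegg", "dn", "up", "network", "corr"})

DEFAULT_STOPWORDS = ENGLISH_STOPWORDS | EXTRA_STOPWORDS
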