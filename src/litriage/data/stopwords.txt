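# PubMed/NCBI stopword list, one term per line.
a
about
again
all
almost
also
although
always
among
an
and
another
any
are
as
at
be
because
been
before
being
between
both
but
by
can
could
did
do
does
done
due
during
each
either
enough
especially
etc
for
found
from
further
had
has
have
having
here
how
however
i
if
in
into
is
it
its
itself
just
kg
km
made
mainly
make
may
mg
might
ml
mm
most
mostly
must
nearly
neither
no
nor
obtained
of
often
on
our
overall
perhaps
pmid
quite
rather
really
regarding
seem
seen
several
should
show
showed
shown
shows
significantly
since
so
some
such
than
that
the
their
theirs
them
then
there
therefore
these
they
this
those
through
thus
to
upon
use
used
using
various
very
was
we
were
what
when
which
while
with
within
without
would
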