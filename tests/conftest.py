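import pytest

from speechlex.simulate import CohortSpec, GroupProfile, default_profiles, generate_cohort
from speechlex.transcripts import Group, Picture


@pytest.fixture(scope="session")
def small_cohort():
    """12-participant cohort (2 per group), both pictures, small vocabulary."""
    spec = CohortSpec(
        group_sizes={g: 2 for g in Group},
        n_words=80,
    )
    return generate_cohort(spec, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the study group sizes (24/9/9/9/10/13), trimmed vocabulary."""
    return generate_cohort(CohortSpec(n_words=200), seed=11)


def make_two_group_spec(n_per_group=20, n_words=120, profiles=None):
    profs = profiles or {
        Group.control: default_profiles()[Group.control],
        Group.svPPA: default_profiles()[Group.svPPA],
    }
    return CohortSpec(
        group_sizes={g: n_per_group for g in profs},
        profiles=profs,
        n_words=n_words,
        pictures=(Picture.cookie_theft,),
    )
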