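"""Built-in name pools and the nickname table for the synthetic population.

Small Anglo-Australian-flavoured pools sampled with a mildly skewed
(Zipf-like, exponent 0.5) frequency distribution. The pools are
deliberately compact: a few hundred distinct values give exact-agreement
collision probabilities (u-probabilities) around 0.8-1%, which is the
regime a five-million-record national registry scaled to desk size
produces. No attempt is made at culturally faithful name frequencies.
"""

from __future__ import annotations

import numpy as np

SURNAMES = [
    "SMITH", "JONES", "WILLIAMS", "BROWN", "WILSON", "TAYLOR", "JOHNSON", "WHITE",
    "MARTIN", "ANDERSON", "THOMPSON", "NGUYEN", "THOMAS", "WALKER", "HARRIS", "LEE",
    "RYAN", "ROBINSON", "KELLY", "KING", "DAVIS", "WRIGHT", "EVANS", "ROBERTS",
    "GREEN", "HALL", "WOOD", "JACKSON", "CLARKE", "PATEL", "KHAN", "LEWIS",
    "JAMES", "PHILLIPS", "MASON", "MITCHELL", "ROSE", "DAVIES", "RODGERS", "COOK",
    "CARTER", "RICHARDSON", "BAILEY", "COOPER", "HILL", "WARD", "MURPHY", "WATSON",
    "BAKER", "HUGHES", "GRAY", "EDWARDS", "SCOTT", "OBRIEN", "STEWART", "MORRIS",
    "TURNER", "PARKER", "COLLINS", "CAMPBELL", "BELL", "MURRAY", "COX", "ELLIS",
    "SIMPSON", "GRANT", "WEBB", "FISHER", "BARNES", "HENDERSON", "LLOYD", "POWELL",
    "PALMER", "MILLS", "HOLMES", "ROGERS", "SHAW", "HUNT", "HARRISON", "GIBSON",
    "KNIGHT", "MARSHALL", "STEVENS", "BUTLER", "PEARSON", "REID", "FOSTER", "DIXON",
    "HART", "PRICE", "BENNETT", "ARMSTRONG", "GRAHAM", "SULLIVAN", "WALLACE", "WOODS",
    "FORD", "WEST", "RILEY", "OWEN", "PERRY", "KENNEDY", "BURNS", "GORDON",
    "DUNCAN", "HAMILTON", "DOYLE", "FLYNN", "BYRNE", "REILLY", "BARKER", "MAY",
    "GEORGE", "HARVEY", "ATKINSON", "LANE", "DEAN", "CHAPMAN", "HAYES", "ROSS",
    "LAWSON", "FRASER", "HOPKINS", "FLEMING", "DAY", "LAWRENCE", "NICHOLSON", "HOLT",
    "WELLS", "CROSS", "HUNTER", "DOUGLAS", "SPENCER", "GARDNER", "CURTIS", "GILBERT",
    "STONE", "BRADLEY", "PAYNE", "NEWMAN", "JENKINS", "BARRETT", "MOLONEY", "BISHOP",
    "HARDY", "PORTER", "BURTON", "COLE", "WATTS", "DALY", "BLACK", "FOX",
    "OCONNOR", "CONNOLLY", "HIGGINS", "CLANCY", "BURKE", "SHEEHAN", "CAREY", "DWYER",
    "MCDONALD", "MCKENZIE", "MACLEAN", "MCGRATH", "MCCARTHY", "MCMAHON", "MCLEOD", "MCKAY",
    "FERGUSON", "CAMERON", "SINCLAIR", "CRAWFORD", "KERR", "DONALDSON", "PATERSON", "LINDSAY",
    "SUTHERLAND", "MILNE", "WALSH", "BRENNAN", "GALLAGHER", "DONNELLY", "KEANE", "HOGAN",
    "WONG", "CHEN", "LIU", "ZHANG", "SINGH", "KAUR", "TRAN", "PHAM",
    "HOFFMANN", "SCHMIDT", "MULLER", "WAGNER", "FISCHER", "WEBER", "BECKER", "SCHULZ",
    "ROSSI", "RUSSO", "ESPOSITO", "ROMANO", "COLOMBO", "RICCI", "GRECO", "CONTI",
]

GIVEN_FEMALE = [
    "JESSICA", "SARAH", "EMMA", "REBECCA", "MICHELLE", "AMANDA", "LAUREN", "KATHERINE",
    "EMILY", "NICOLE", "STEPHANIE", "MELISSA", "RACHEL", "SAMANTHA", "LISA", "HANNAH",
    "KAYLA", "AMY", "COURTNEY", "DANIELLE", "JENNIFER", "ASHLEY", "BRITTANY", "MEGAN",
    "CHLOE", "SOPHIE", "OLIVIA", "GEORGIA", "ALICE", "GRACE", "HOLLY", "PAIGE",
    "SHANNON", "KIRSTY", "NATALIE", "CASSANDRA", "ALEXANDRA", "VICTORIA", "ELIZABETH", "CLAIRE",
    "KATE", "LEAH", "ERIN", "CAITLIN", "TAYLA", "JADE", "BROOKE", "SHAKIRA",
    "TANYA", "KAREN", "SUSAN", "JULIE", "DONNA", "LEANNE", "SHARON", "TRACEY",
    "KYLIE", "NARELLE", "RENEE", "KIMBERLEY", "CRYSTAL", "TIFFANY", "EBONY", "SIENNA",
    "RUBY", "CHELSEA", "MADISON", "ZOE", "ISABELLA", "CHARLOTTE", "AMBER", "SKYE",
    "TAHLIA", "MIA", "IMOGEN", "BRONWYN", "CARLY", "HAYLEY", "KRYSTAL", "MARLEY",
    "JASMINE", "DESTINY", "SHAE", "KEIRA", "TALIA", "MACKENZIE", "INDIA", "HARMONY",
    "ANGELA", "CHRISTINA", "VANESSA", "MARIA", "HELEN", "CATHERINE", "MARGARET", "ANNE",
    "DIANE", "JANET", "CAROL", "JOANNE", "DEBORAH", "PATRICIA", "LINDA", "BARBARA",
    "KERRY", "ROBYN", "GAIL", "WENDY", "DENISE", "GLENDA", "RHONDA", "CHERYL",
    "LATISHA", "SHANIA", "KIARA", "ALINTA", "JEDDA", "MARLEE", "YINDI", "TALEISHA",
]

GIVEN_MALE = [
    "MICHAEL", "DANIEL", "MATTHEW", "JOSHUA", "ANDREW", "JAMES", "DAVID", "LUKE",
    "RYAN", "BENJAMIN", "SAMUEL", "NICHOLAS", "THOMAS", "JACK", "ADAM", "CHRISTOPHER",
    "JOHN", "TIMOTHY", "JASON", "DYLAN", "JORDAN", "NATHAN", "AARON", "BRADLEY",
    "WILLIAM", "ROBERT", "ANTHONY", "MARK", "SHANE", "JACOB", "ALEXANDER", "SCOTT",
    "STEVEN", "PAUL", "PETER", "RICHARD", "SHAUN", "TRAVIS", "BRENDAN", "CAMERON",
    "MITCHELL", "JAKE", "CONNOR", "LIAM", "KYLE", "TYLER", "ZACHARY", "BRANDON",
    "CODY", "HAYDEN", "LACHLAN", "BLAKE", "JAI", "COREY", "JESSE", "DARREN",
    "WAYNE", "CRAIG", "GLENN", "TROY", "DEAN", "GRANT", "BRETT", "KEVIN",
    "GARY", "STUART", "NEIL", "IAN", "COLIN", "BARRY", "TERRY", "RODNEY",
    "ETHAN", "NOAH", "OLIVER", "HARRISON", "ISAAC", "XAVIER", "COOPER", "ANGUS",
    "PATRICK", "SEAN", "KIERAN", "DECLAN", "CONOR", "RHYS", "OWEN", "EVAN",
    "JARRAH", "KOOPARU", "MONTY", "CLANCY", "BAILEY", "DUSTIN", "HEATH", "CLINTON",
    "ALAN", "BRUCE", "GEOFFREY", "GRAHAM", "KENNETH", "LEONARD", "MALCOLM", "NORMAN",
    "RAYMOND", "RONALD", "STANLEY", "TREVOR", "VINCENT", "WARREN", "BERNARD", "CECIL",
    "TYSON", "JAYDEN", "KODY", "BRAYDEN", "RRYAN", "JARROD", "NATE", "TODD",
]

#: Common-form substitutions used when generating first-name aliases.
NICKNAMES = {
    "WILLIAM": "BILL", "ROBERT": "BOB", "RICHARD": "DICK", "MICHAEL": "MICK",
    "CHRISTOPHER": "CHRIS", "NICHOLAS": "NICK", "BENJAMIN": "BEN", "SAMUEL": "SAM",
    "DANIEL": "DANNY", "MATTHEW": "MATT", "JOSHUA": "JOSH", "ANDREW": "ANDY",
    "TIMOTHY": "TIM", "ANTHONY": "TONY", "STEVEN": "STEVE", "PETER": "PETE",
    "ALEXANDER": "ALEX", "ZACHARY": "ZAC", "PATRICK": "PADDY", "KENNETH": "KEN",
    "LEONARD": "LEN", "RAYMOND": "RAY", "RONALD": "RON", "TREVOR": "TREV",
    "GEOFFREY": "GEOFF", "BRADLEY": "BRAD", "THOMAS": "TOM", "JAMES": "JIM",
    "EDWARD": "TED", "LACHLAN": "LOCKIE", "HARRISON": "HARRY", "CAMERON": "CAM",
    "JESSICA": "JESS", "REBECCA": "BEC", "KATHERINE": "KATE", "ELIZABETH": "LIZ",
    "STEPHANIE": "STEPH", "SAMANTHA": "SAM", "DANIELLE": "DANI", "JENNIFER": "JEN",
    "ALEXANDRA": "LEXIE", "VICTORIA": "VICKY", "CASSANDRA": "CASS", "MELISSA": "MEL",
    "KIMBERLEY": "KIM", "CHRISTINA": "TINA", "PATRICIA": "TRISH", "MARGARET": "MAGGIE",
    "DEBORAH": "DEB", "BRONWYN": "BRON", "ISABELLA": "BELLA", "CHARLOTTE": "LOTTIE",
    "MADISON": "MADDIE", "MACKENZIE": "KENZIE", "NATALIE": "NAT", "CATHERINE": "CATHY",
}

#: Australian state/territory registration codes with rough cohort-relevant
#: weights (the justice cohort is Queensland-based; deaths register anywhere).
STATE_CODES = ["QLD", "NSW", "VIC", "WA", "SA", "TAS", "NT", "ACT"]
STATE_WEIGHTS = [0.55, 0.16, 0.12, 0.06, 0.05, 0.02, 0.03, 0.01]


def zipf_weights(n: int, exponent: float = 0.5) -> np.ndarray:
    """Normalised rank-frequency weights ``rank**-exponent`` for a pool."""
    w = np.arange(1, n + 1, dtype=float) ** -exponent
    return w / w.sum()


def sample_names(rng: np.random.Generator, pool: list[str], size: int) -> np.ndarray:
    """Sample ``size`` names from ``pool`` with the standard skewed weights."""
    idx = rng.choice(len(pool), size=size, p=zipf_weights(len(pool)))
    return np.asarray(pool, dtype=object)[idx]
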