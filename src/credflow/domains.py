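"""Registered-domain normalization for URL -> domain-list matching.

Low-credibility domain lists (Iffy+-style) carry registrable domains such as
``rt.com`` or ``childrenshealthdefense.org``.  Matching therefore collapses
every URL to its public-suffix-aware registered domain: the label directly
left of the public suffix, plus the suffix itself.  A curated table of the
common multi-part country-code suffixes (``co.uk``, ``com.au``, ...) handles
hosts whose registrable part spans three labels; every other host registers
at the final two labels.
"""

from __future__ import annotations

import ipaddress
from urllib.parse import urlsplit

#: Sentinel returned for URLs that cannot be parsed into a hostname.
INVALID_DOMAIN = "invalid"

# Common multi-part public suffixes. Registrable domains under these span
# one extra label (bbc.co.uk, smh.com.au). Not exhaustive; unknown
# second-level suffixes fall back to the two-label rule.
_MULTI_PART_SUFFIXES = frozenset(
    {
        "co.uk", "org.uk", "ac.uk", "gov.uk", "me.uk", "net.uk", "ltd.uk",
        "plc.uk", "sch.uk", "nhs.uk",
        "com.au", "net.au", "org.au", "edu.au", "gov.au", "id.au", "asn.au",
        "co.nz", "net.nz", "org.nz", "govt.nz", "ac.nz", "geek.nz",
        "co.jp", "ne.jp", "or.jp", "ac.jp", "go.jp", "ad.jp",
        "co.kr", "or.kr", "go.kr", "ac.kr",
        "com.br", "org.br", "net.br", "gov.br", "edu.br",
        "com.mx", "org.mx", "gob.mx", "edu.mx",
        "com.ar", "org.ar", "gob.ar", "edu.ar",
        "co.in", "net.in", "org.in", "gov.in", "ac.in", "firm.in",
        "com.cn", "net.cn", "org.cn", "gov.cn", "edu.cn",
        "com.tw", "org.tw", "gov.tw", "edu.tw",
        "com.hk", "org.hk", "gov.hk", "edu.hk",
        "com.sg", "org.sg", "gov.sg", "edu.sg",
        "co.za", "org.za", "gov.za", "web.za", "ac.za",
        "com.tr", "org.tr", "gov.tr", "edu.tr",
        "com.eg", "org.eg", "gov.eg",
        "com.sa", "org.sa", "gov.sa", "edu.sa",
        "com.pk", "org.pk", "gov.pk", "edu.pk",
        "com.ng", "org.ng", "gov.ng",
        "co.ke", "or.ke", "go.ke", "ac.ke",
        "com.my", "org.my", "gov.my", "edu.my",
        "co.id", "or.id", "go.id", "web.id", "ac.id",
        "com.ph", "org.ph", "gov.ph", "edu.ph",
        "com.vn", "org.vn", "gov.vn", "edu.vn",
        "co.th", "or.th", "go.th", "ac.th", "in.th",
        "com.ua", "org.ua", "gov.ua", "net.ua", "edu.ua",
        "com.pl", "org.pl", "net.pl", "edu.pl", "gov.pl",
        "co.il", "org.il", "gov.il", "ac.il", "net.il", "muni.il",
        "com.co", "org.co", "gov.co", "edu.co", "net.co",
        "com.pe", "org.pe", "gob.pe", "edu.pe",
        "com.ec", "org.ec", "gob.ec", "edu.ec",
        "com.uy", "org.uy", "gub.uy", "edu.uy",
        "com.ve", "org.ve", "gob.ve",
        "com.do", "org.do", "gob.do",
        "com.gt", "org.gt", "gob.gt",
        "com.bo", "org.bo", "gob.bo",
        "com.py", "org.py", "gov.py",
        "com.ni", "org.ni", "gob.ni",
        "com.sv", "org.sv", "gob.sv",
        "com.hn", "org.hn", "gob.hn",
        "com.pa", "org.pa", "gob.pa",
        "com.cu", "org.cu", "gob.cu",
        "co.cr", "or.cr", "go.cr", "ac.cr",
        "co.cl", "gob.cl", "gov.cl",
        "com.bd", "org.bd", "gov.bd", "edu.bd",
        "com.np", "org.np", "gov.np", "edu.np",
        "com.lk", "org.lk", "gov.lk", "edu.lk",
        "com.kw", "org.kw", "gov.kw", "edu.kw",
        "com.qa", "org.qa", "gov.qa", "edu.qa",
        "com.bh", "org.bh", "gov.bh",
        "com.om", "org.om", "gov.om",
        "com.jo", "org.jo", "gov.jo", "edu.jo",
        "com.lb", "org.lb", "gov.lb", "edu.lb",
        "com.dz", "org.dz", "gov.dz",
        "co.ma", "org.ma", "gov.ma", "ac.ma",
        "com.tn", "org.tn", "gov.tn",
        "com.ly", "org.ly", "gov.ly",
        "com.et", "org.et", "gov.et",
        "co.tz", "or.tz", "go.tz", "ac.tz",
        "co.ug", "or.ug", "go.ug", "ac.ug",
        "co.zw", "org.zw", "gov.zw", "ac.zw",
        "com.gh", "org.gh", "gov.gh", "edu.gh",
        "com.cm", "org.cm", "gov.cm",
        "com.ci", "org.ci", "gov.ci",
        "com.ru", "org.ru", "net.ru", "gov.ru", "edu.ru", "msk.ru", "spb.ru",
        "com.by", "org.by", "gov.by",
        "com.kz", "org.kz", "gov.kz", "edu.kz",
        "com.uz", "org.uz", "gov.uz",
        "com.az", "org.az", "gov.az",
        "com.ge", "org.ge", "gov.ge", "edu.ge",
        "com.am", "org.am",
        "com.mt", "org.mt", "gov.mt", "edu.mt",
        "com.cy", "org.cy", "gov.cy",
        "com.gr", "org.gr", "gov.gr", "edu.gr",
        "com.pt", "org.pt", "gov.pt", "edu.pt",
        "com.es", "org.es", "gob.es", "edu.es", "nom.es",
        "com.fr", "gouv.fr", "asso.fr", "nom.fr",
        "co.it", "gov.it", "edu.it",
        "co.at", "or.at", "gv.at", "ac.at",
        "com.de",
        "co.nl",
        "com.se", "org.se",
        "co.no",
        "com.fi",
        "com.ee", "org.ee", "gov.ee", "edu.ee",
        "com.lv", "org.lv", "gov.lv", "edu.lv",
        "com.lt", "org.lt", "gov.lt",
        "com.ro", "org.ro", "gov.ro", "edu.ro",
        "com.bg", "org.bg", "gov.bg",
        "com.hr", "org.hr", "gov.hr",
        "com.rs", "org.rs", "gov.rs", "edu.rs", "co.rs", "in.rs",
        "com.si",
        "com.sk",
        "com.cz",
        "com.hu", "org.hu", "gov.hu", "edu.hu", "co.hu", "info.hu",
        "co.ir", "org.ir", "gov.ir", "ac.ir",
        "com.iq", "org.iq", "gov.iq", "edu.iq",
        "com.sy", "org.sy", "gov.sy",
        "com.ye", "org.ye", "gov.ye",
        "com.af", "org.af", "gov.af", "edu.af",
        "com.kh", "org.kh", "gov.kh", "edu.kh",
        "com.la",
        "com.mm", "org.mm", "gov.mm", "edu.mm",
        "com.mo", "org.mo", "gov.mo", "edu.mo",
        "com.mv", "org.mv", "gov.mv",
        "com.bn", "org.bn", "gov.bn", "edu.bn",
        "com.fj", "org.fj", "gov.fj", "ac.fj",
        "com.pg", "org.pg", "gov.pg",
        "com.sb",
        "com.vu",
        "com.ws",
        "com.to", "gov.to",
        "com.ki",
        "com.nf",
        "co.ck", "org.ck", "gov.ck",
        "com.ag", "org.ag",
        "com.bs", "org.bs",
        "com.bb", "org.bb", "gov.bb",
        "com.bz", "org.bz", "gov.bz",
        "com.jm", "org.jm", "gov.jm", "edu.jm",
        "com.tt", "org.tt", "gov.tt",
        "com.gy", "org.gy",
        "com.sr",
        "com.pr", "org.pr", "gov.pr",
        "com.ht", "org.ht",
        "com.mk", "org.mk", "gov.mk", "edu.mk",
        "com.al", "org.al", "gov.al", "edu.al",
        "com.ba", "org.ba", "gov.ba", "edu.ba",
        "com.md", "org.md",
        "com.mc",
        "co.gg", "org.gg", "net.gg",
        "co.je", "org.je", "net.je",
        "co.im", "org.im", "net.im",
        "com.is",
        "com.lu",
        "com.li",
    }
)


def normalize_domain(url: str) -> str:
    """Collapse an absolute URL to its lowercase registered domain.

    Scheme, credentials, port, path, query, fragment, and a leading
    ``www.`` are stripped; subdomains collapse to the registrable domain
    (``news.childrenshealthdefense.org`` -> ``childrenshealthdefense.org``,
    ``https://example.co.uk/p`` -> ``example.co.uk``).  Unparseable URLs
    return :data:`INVALID_DOMAIN`; IP-literal hosts are returned verbatim.
    """
    if not isinstance(url, str) or not url.strip():
        return INVALID_DOMAIN
    try:
        host = urlsplit(url.strip()).hostname
    except ValueError:
        return INVALID_DOMAIN
    if not host:
        return INVALID_DOMAIN
    host = host.lower().rstrip(".")
    try:
        ipaddress.ip_address(host)
        return host
    except ValueError:
        pass
    if host.startswith("www."):
        host = host[4:]
    labels = host.split(".")
    if len(labels) < 2 or any(not lab for lab in labels):
        return INVALID_DOMAIN if len(labels) < 2 or "" in labels else host
    if len(labels) >= 3 and ".".join(labels[-2:]) in _MULTI_PART_SUFFIXES:
        return ".".join(labels[-3:])
    return ".".join(labels[-2:])


def normalize_domain_list(domains) -> set[str]:
    """Normalize a plain domain list (no scheme needed) to registered domains."""
    out = set()
    for d in domains:
        d = d.strip().lower()
        if not d:
            continue
        norm = normalize_domain(f"https://{d}/")
        if norm != INVALID_DOMAIN:
            out.add(norm)
    return out
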