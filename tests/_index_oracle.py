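"""Independent straight-line re-implementation of the 21 vegetation-index
formulas, written from the printed definitions without any shared code,
used as a second-implementer oracle in tests."""


def arvi(r450, r550, r670, r720, r800):
    return (r800 - (2 * r670 - r450)) / (r800 + r670 + 0.5)


def cari(r450, r550, r670, r720, r800):
    return (r670 - r450) - (r670 - r800)


def cci2(r450, r550, r670, r720, r800):
    return (r800 - r670) / (r800 + r670 + 0.1)


def cigreen(r450, r550, r670, r720, r800):
    return r800 / r550 - 1


def cirededge(r450, r550, r670, r720, r800):
    return r800 / r720 - 1


def cndvi(r450, r550, r670, r720, r800):
    return ((r800 - r670) - (r800 - r450)) / ((r800 - r670) + (r800 - r450))


def cvi(r450, r550, r670, r720, r800):
    return r800**2 / r670


def cvi2(r450, r550, r670, r720, r800):
    return r800 / (r720 + 1)


def dvi(r450, r550, r670, r720, r800):
    return r800 - r670


def evi(r450, r550, r670, r720, r800):
    return 2.5 * (r800 - r670) / (r800 + 6 * r670 - 7.5 * r450 + 1)


def gndvi(r450, r550, r670, r720, r800):
    return (r800 - r550) / (r800 + r550)


def mcari(r450, r550, r670, r720, r800):
    return ((r670 - r450) - (r670 - r800)) / r670


def ndre(r450, r550, r670, r720, r800):
    return (r800 - r720) / (r800 + r720)


def ndvi(r450, r550, r670, r720, r800):
    return (r800 - r670) / (r800 + r670)


def nli(r450, r550, r670, r720, r800):
    return r800 / (r670 + r550)


def pvi(r450, r550, r670, r720, r800):
    return (r800 - r670) - 0.5 * (r800 + r670)


def rvi(r450, r550, r670, r720, r800):
    return r800 / r670


def savi(r450, r550, r670, r720, r800):
    return 2.5 * (r800 - r670) / (r800 + r670 + 0.5)


def tgi(r450, r550, r670, r720, r800):
    return r550 - 0.39 * r670 - 0.61 * r450


def vari(r450, r550, r670, r720, r800):
    return (r550 - r670) / (r550 + r670 - r450)


def vig(r450, r550, r670, r720, r800):
    return (r800 - (2 * r670 + r450)) / (r800 + (2 * r670 + r450))


ORACLE = {
    "ARVI": arvi,
    "CARI": cari,
    "CCI2": cci2,
    "CIgreen": cigreen,
    "CIrededge": cirededge,
    "CNDVI": cndvi,
    "CVI": cvi,
    "CVI2": cvi2,
    "DVI": dvi,
    "EVI": evi,
    "GNDVI": gndvi,
    "MCARI": mcari,
    "NDRE": ndre,
    "NDVI": ndvi,
    "NLI": nli,
    "PVI": pvi,
    "RVI": rvi,
    "SAVI": savi,
    "TGI": tgi,
    "VARI": vari,
    "VIG": vig,
}
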