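# Place names erroneously tagged as person names; lower-case, one per line.
albuquerque
arizona
arvada
aurora
boulder
brighton
broomfield
california
centennial
chicago
cleveland
colorado
dallas
dayton
denver
detroit
durango
england
englewood
florida
fort collins
georgia
golden
greeley
houston
idaho
illinois
kansas
lakewood
littleton
longmont
louisville
loveland
memphis
mexico
miami
michigan
minnesota
missouri
montana
nebraska
nevada
oklahoma
omaha
oregon
orlando
phoenix
portland
pueblo
sacramento
seattle
tennessee
texas
thornton
toledo
tucson
utah
vermont
virginia
westminster
wyoming
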