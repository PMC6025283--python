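"""PubMed XML parsing, the line-delimited fixture format, and Entrez paging."""

import io

import pytest

from meshnet.corpus_io import (
    Corpus,
    EntrezError,
    FixtureFormatError,
    MeshHeading,
    ParseError,
    PublicationRecord,
    fetch_entrez,
    parse_pubmed_xml,
    read_fixture,
    write_fixture,
)

SINGLE_CITATION = """<?xml version="1.0"?>
<PubmedArticleSet>
 <PubmedArticle>
  <MedlineCitation>
   <PMID>12345</PMID>
   <Article>
    <Journal><JournalIssue><PubDate><Year>2016</Year></PubDate></JournalIssue></Journal>
    <ArticleTitle>Immune checkpoint blockade in melanoma</ArticleTitle>
   </Article>
   <MeshHeadingList>
    <MeshHeading>
     <DescriptorName MajorTopicYN="Y">Melanoma</DescriptorName>
     <QualifierName>therapy</QualifierName>
     <QualifierName>immunology</QualifierName>
    </MeshHeading>
    <MeshHeading>
     <DescriptorName MajorTopicYN="N">Immunotherapy</DescriptorName>
    </MeshHeading>
   </MeshHeadingList>
  </MedlineCitation>
 </PubmedArticle>
</PubmedArticleSet>
"""


def _citation(pmid, pubdate_xml="<Year>2016</Year>", extra="", mesh=""):
    return f"""<PubmedArticle><MedlineCitation>
      <PMID>{pmid}</PMID>{extra}
      <Article>
        <Journal><JournalIssue><PubDate>{pubdate_xml}</PubDate></JournalIssue></Journal>
        <ArticleTitle>Title {pmid}</ArticleTitle>
      </Article>{mesh}
    </MedlineCitation></PubmedArticle>"""


def _doc(*citations):
    return "<PubmedArticleSet>" + "".join(citations) + "</PubmedArticleSet>"


class TestParsePubmedXml:
    def test_single_citation_fields(self):
        corpus = parse_pubmed_xml(SINGLE_CITATION)
        assert len(corpus) == 1
        rec = corpus.records[0]
        assert rec.pmid == "12345"
        assert rec.year == 2016
        assert len(rec.headings) == 2
        assert rec.headings[0] == MeshHeading(
            "Melanoma", ("therapy", "immunology"), major_topic=True
        )
        assert rec.headings[1].descriptor == "Immunotherapy"

    def test_empty_document_warns_not_errors(self):
        with pytest.warns(UserWarning, match="no citations"):
            corpus = parse_pubmed_xml("<PubmedArticleSet></PubmedArticleSet>")
        assert len(corpus) == 0

    def test_missing_mesh_heading_list_gives_empty_headings(self):
        corpus = parse_pubmed_xml(_doc(_citation("7")))
        assert corpus.records[0].headings == ()

    @pytest.mark.parametrize(
        "pubdate_xml, extra, expected_year",
        [
            ("<Year>2014</Year>", "", 2014),
            ("<MedlineDate>2015 Jan-Feb</MedlineDate>", "", 2015),
            ("", "<DateCompleted><Year>2013</Year></DateCompleted>", 2013),
        ],
    )
    def test_year_resolution_chain(self, pubdate_xml, extra, expected_year):
        corpus = parse_pubmed_xml(_doc(_citation("9", pubdate_xml, extra)))
        assert corpus.records[0].year == expected_year

    def test_unresolvable_year_dropped_and_accounted(self):
        doc = _doc(_citation("1"), _citation("2", pubdate_xml=""), _citation("3"))
        corpus = parse_pubmed_xml(doc)
        assert [r.pmid for r in corpus.records] == ["1", "3"]
        report = corpus.report
        assert report.n_citations == 3
        assert report.n_dropped_no_year == 1
        assert report.n_parsed + report.n_dropped == report.n_citations

    def test_malformed_xml_names_position(self):
        with pytest.raises(ParseError, match=r"line \d+"):
            parse_pubmed_xml("<PubmedArticleSet><broken")


class TestFixtureFormat:
    def _corpus(self):
        return Corpus(
            [
                PublicationRecord(
                    "1", "Tumor immunology — a review", 2015,
                    (MeshHeading("Neoplasms", ("immunology",)),),
                ),
                PublicationRecord("2", "Title\twith tab", 2016),
                PublicationRecord("3", "", 2014, (MeshHeading("Humans"),)),
            ],
            provenance="unit-test",
        )

    def test_round_trip_preserves_every_field(self, tmp_path):
        path = tmp_path / "corpus.jsonl"
        original = self._corpus()
        write_fixture(original, path)
        back = read_fixture(path)
        assert back.records == original.records

    def test_empty_file_gives_empty_corpus(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert len(read_fixture(path)) == 0

    def test_missing_year_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(
            '{"pmid": "1", "year": 2015, "title": "ok", "headings": []}\n'
            '{"pmid": "2", "title": "no year", "headings": []}\n'
        )
        with pytest.raises(FixtureFormatError, match="line 2: missing year"):
            read_fixture(path)

    def test_invalid_json_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text("not json\n")
        with pytest.raises(FixtureFormatError, match="line 1"):
            read_fixture(path)


class TestCorpusInvariants:
    def test_duplicate_pmid_rejected(self):
        records = [
            PublicationRecord("1", "a", 2015),
            PublicationRecord("1", "b", 2016),
        ]
        with pytest.raises(ValueError, match="duplicate pmid"):
            Corpus(records)

    def test_duplicate_qualifiers_rejected(self):
        with pytest.raises(ValueError, match="duplicate qualifiers"):
            MeshHeading("Neoplasms", ("therapy", "therapy"))

    def test_implausible_year_rejected(self):
        with pytest.raises(ValueError, match="implausible year"):
            PublicationRecord("1", "t", 1500)


class TestEntrezPaging:
    """Retrieval contract against a local mock service; no network."""

    def _mock_service(self, n_ids, fail_pages=0):
        calls = {"efetch": 0}
        ids = [str(i) for i in range(n_ids)]

        def esearch(query, contact):
            return ids

        def efetch(page, contact):
            calls["efetch"] += 1
            if calls["efetch"] <= fail_pages:
                raise OSError("service unavailable")
            return _doc(*(_citation(p) for p in page)).encode()

        return esearch, efetch, calls

    def test_paging_250_ids_in_3_requests(self):
        esearch, efetch, calls = self._mock_service(250)
        corpus = fetch_entrez("q", {}, page_size=100, esearch=esearch, efetch=efetch)
        assert calls["efetch"] == 3
        assert len(corpus) == 250

    def test_zero_ids_gives_empty_corpus(self):
        esearch, efetch, _ = self._mock_service(0)
        corpus = fetch_entrez("q", {}, esearch=esearch, efetch=efetch)
        assert len(corpus) == 0

    def test_transient_failure_retried_then_succeeds(self):
        esearch, efetch, calls = self._mock_service(5, fail_pages=2)
        corpus = fetch_entrez("q", {}, esearch=esearch, efetch=efetch, max_attempts=3)
        assert len(corpus) == 5
        assert calls["efetch"] == 3

    def test_persistent_failure_never_partial(self):
        esearch, efetch, _ = self._mock_service(150, fail_pages=99)
        with pytest.raises(EntrezError, match="after 3 attempts"):
            fetch_entrez("q", {}, page_size=100, esearch=esearch, efetch=efetch)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            fetch_entrez("", {})
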