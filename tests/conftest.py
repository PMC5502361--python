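import datetime as dt

import pytest

from litriage import Document, DocumentSet, Thesaurus, load_thesaurus


@pytest.fixture
def ptm_minimal() -> Thesaurus:
    """A two-concept PTM thesaurus for focused annotation tests."""
    table = (
        "concept_id\tlabel\tstems\tcategory\n"
        "PTM:P\tphosphorylation\tphosphorylat\tptm_type\n"
        "PTM:U\tubiquitination\tubiquitinat\tptm_type\n"
    )
    return load_thesaurus(table, "PTM")


@pytest.fixture
def small_corpus() -> DocumentSet:
    """Three dated documents with distinct term distributions."""
    return DocumentSet([
        Document(1, "alpha binds beta", "alpha alpha complex", dt.date(2001, 1, 1)),
        Document(2, "gamma study", "gamma gamma gamma", dt.date(2010, 6, 1)),
        Document(3, "alpha review", "unrelated text here", dt.date(2005, 3, 1),
                 pub_types=frozenset({"Review"})),
    ])


MEDLINE_XML_THREE = b"""<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>101</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>2011</Year><Month>Mar</Month></PubDate></JournalIssue></Journal>
        <ArticleTitle>BTK phosphorylates PLCG2</ArticleTitle>
        <Abstract>
          <AbstractText Label="BACKGROUND">Kinase signalling.</AbstractText>
          <AbstractText Label="RESULTS">BTK binds PLCG2.</AbstractText>
        </Abstract>
        <PublicationTypeList><PublicationType>Journal Article</PublicationType></PublicationTypeList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>102</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>2014</Year></PubDate></JournalIssue></Journal>
        <ArticleTitle>A survey of kinases</ArticleTitle>
        <Abstract><AbstractText>Overview of kinase biology.</AbstractText></Abstract>
        <PublicationTypeList><PublicationType>Review</PublicationType></PublicationTypeList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>103</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><MedlineDate>1999 Dec-2000 Jan</MedlineDate></PubDate></JournalIssue></Journal>
        <ArticleTitle>No abstract here</ArticleTitle>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""
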